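"""Distribution of phased variants relative to CpGs, islands and genes.

A read can reveal the allelic origin of a CpG only when it spans both
the CpG and a phased heterozygous variant (PHV), so the reach of the
method is governed by the distance from each CpG (or island center) to
its nearest PHV, and ASE is further limited to the minority of PHVs that
fall inside exons.  This module computes those distance and genic-
context statistics for any variant set and annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .haplotyping import PhasedVariant

__all__ = [
    "nearest_phv_distance",
    "fraction_within",
    "classify_phvs",
    "interval_center",
]


def interval_center(start: int, end: int) -> int:
    """Integer center of a 0-based half-open interval (floor of midpoint)."""
    return (start + end) // 2


def nearest_phv_distance(
    sites: Sequence,
    variants: Iterable[PhasedVariant],
) -> np.ndarray:
    """Distance (bp) from each site to its nearest phased variant.

    ``sites`` are either (chrom, pos) points or (chrom, start, end)
    intervals; interval distance is measured from the integer center.
    A site on a chromosome with no variant gets ``inf``.
    """
    by_chrom: dict[str, list[int]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    sorted_pos = {c: np.sort(np.array(p)) for c, p in by_chrom.items()}

    out = np.empty(len(sites))
    for i, site in enumerate(sites):
        if len(site) == 2:
            chrom, pos = site
        else:
            chrom, start, end = site
            pos = interval_center(start, end)
        arr = sorted_pos.get(chrom)
        if arr is None or not len(arr):
            out[i] = np.inf
            continue
        j = np.searchsorted(arr, pos)
        cands = arr[max(0, j - 1) : j + 1]
        out[i] = np.min(np.abs(cands - pos))
    return out


def fraction_within(
    distances: Sequence[float], cutoffs: Sequence[float]
) -> pd.DataFrame:
    """Fraction of sites whose nearest-PHV distance is <= each cutoff.

    These are the fractions of CpGs whose allelic origin is resolvable
    with reads of (at most) the cutoff length.  Returns an empty table
    for empty input; fractions are non-decreasing in the cutoff.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        return pd.DataFrame(columns=["cutoff", "fraction"])
    rows = [(c, float(np.mean(d <= c))) for c in cutoffs]
    return pd.DataFrame(rows, columns=["cutoff", "fraction"])


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching (start, end) rows; assumes 2-col array."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    merged = []
    cur_s, cur_e = intervals[order[0]]
    for s, e in intervals[order[1:]]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    return np.array(merged)


def _in_any(pos: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean mask: position falls inside any merged half-open interval."""
    if len(merged) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(merged[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < merged[idx[ok], 1]
    return res


def classify_phvs(
    variants: Iterable[PhasedVariant],
    exons: pd.DataFrame,
    genes: pd.DataFrame,
    genome_length: dict[str, int] | int,
) -> dict:
    """Assign each variant a genic context and compute per-kbp densities.

    Precedence is exon > intron > intergenic across overlapping
    annotations: a variant inside any exon is exonic, else inside any
    gene span it is intronic, else intergenic.  ``exons`` and ``genes``
    need columns ``chrom`` (optional if ``genome_length`` is an int for a
    single unnamed chromosome), ``start``, ``end``.

    Returns proportions (summing to 1), counts, category lengths in bp
    (on merged intervals) and densities per kbp.
    """
    variants = list(variants)
    for df, name in ((exons, "exons"), (genes, "genes")):
        missing = {"start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"{name} table contains empty/inverted intervals")

    if isinstance(genome_length, int):
        chroms = sorted({v.chrom for v in variants}) or ["chr1"]
        genome_length = {c: genome_length for c in chroms}

    def _per_chrom(df: pd.DataFrame) -> dict[str, np.ndarray]:
        if "chrom" in df.columns:
            return {
                str(c): _merge_intervals(g[["start", "end"]].to_numpy())
                for c, g in df.groupby("chrom")
            }
        merged = _merge_intervals(df[["start", "end"]].to_numpy())
        return {c: merged for c in genome_length}

    exon_iv = _per_chrom(exons)
    gene_iv = _per_chrom(genes)

    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    assignments = []
    for chrom in sorted({v.chrom for v in variants}):
        pos = np.array([v.pos for v in variants if v.chrom == chrom])
        in_exon = _in_any(pos, exon_iv.get(chrom, np.empty((0, 2))))
        in_gene = _in_any(pos, gene_iv.get(chrom, np.empty((0, 2))))
        cat = np.where(in_exon, "exonic", np.where(in_gene, "intronic", "intergenic"))
        for p, c in zip(pos, cat):
            assignments.append((chrom, int(p), str(c)))
        for c in ("exonic", "intronic", "intergenic"):
            counts[c] += int(np.sum(cat == c))

    n = len(variants)
    proportions = {k: (v / n if n else 0.0) for k, v in counts.items()}

    lengths = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for chrom, L in genome_length.items():
        ex = exon_iv.get(chrom, np.empty((0, 2)))
        gn = gene_iv.get(chrom, np.empty((0, 2)))
        exon_len = int(np.sum(ex[:, 1] - ex[:, 0])) if len(ex) else 0
        gene_len = int(np.sum(gn[:, 1] - gn[:, 0])) if len(gn) else 0
        lengths["exonic"] += exon_len
        lengths["intronic"] += gene_len - _overlap_length(gn, ex)
        lengths["intergenic"] += L - gene_len

    densities = {
        k: (counts[k] / lengths[k] * 1000.0 if lengths[k] > 0 else float("nan"))
        for k in counts
    }
    return {
        "assignments": pd.DataFrame(
            assignments, columns=["chrom", "pos", "category"]
        ),
        "counts": counts,
        "proportions": proportions,
        "lengths_bp": lengths,
        "density_per_kbp": densities,
    }


def _overlap_length(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap (bp) between two merged interval sets."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += int(hi - lo)
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return total
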