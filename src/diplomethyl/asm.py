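"""Allele-specific methylation (ASM) calling over CpG islands.

Each CpG island (CGI) is scored per haplotype as the unweighted mean of
its binary per-CpG methylation calls (methylated = 1); the absolute
difference between the two haplotype scores is the ASM statistic.  A CGI
is called ASM when it passes the island-size filter (>= 30 CpGs), the
per-haplotype coverage filter (mean coverage over called sites >= 16 on
each haplotype), and its score difference reaches the threshold — either
a fixed cutoff (0.68, the value at the top-1% quantile in the reference
sample) or the top quantile recomputed on the sample at hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .methylation import METHYLATED, NOCALL, CpGCall

__all__ = [
    "CGIRecord",
    "ASMRecord",
    "ASMParams",
    "cgi_methylation_score",
    "asm_scan",
    "swap_alleles",
]


@dataclass(frozen=True)
class CGIRecord:
    """A CpG island interval (0-based half-open) with its CpG count."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty CGI interval {self.start}..{self.end}")
        if self.n_cpg < 0:
            raise ValueError("n_cpg must be >= 0")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ASMRecord:
    """Per-CGI methylation scores and the ASM verdict.

    Scores are NaN when every site on that haplotype is NOCALL;
    ``abs_diff`` is defined only when both scores are.
    """

    cgi: CGIRecord
    score_a: float
    score_b: float
    abs_diff: float
    coverage_ok: bool
    is_asm: bool
    nearest_phv_distance: float = float("nan")


@dataclass(frozen=True)
class ASMParams:
    """Filters and threshold of the ASM scan.

    ``coverage_rule`` selects how the >=16x per-haplotype requirement is
    aggregated over an island's called sites: ``"mean"`` (default,
    robust to single-site dropouts) or ``"min"``.
    ``top_quantile`` switches to sample-quantile mode: the threshold
    becomes the value selecting that fraction of eligible islands.
    """

    min_cpgs: int = 30
    min_coverage: float = 16.0
    diff_threshold: float = 0.68
    top_quantile: float | None = None
    coverage_rule: str = "mean"

    def __post_init__(self) -> None:
        if self.coverage_rule not in ("mean", "min"):
            raise ValueError(f"unknown coverage_rule {self.coverage_rule!r}")
        if self.top_quantile is not None and not 0 < self.top_quantile <= 1:
            raise ValueError("top_quantile must be in (0, 1]")


def cgi_methylation_score(calls: Sequence[CpGCall]) -> float:
    """Mean methylation state (methylated = 1) over non-NOCALL sites.

    Returns NaN when no site has a call — the UNDEFINED score.
    """
    states = [c.state for c in calls if c.state != NOCALL]
    if not states:
        return float("nan")
    return sum(s == METHYLATED for s in states) / len(states)


def _aggregate_coverage(calls: Sequence[CpGCall], rule: str) -> float:
    covs = [c.coverage for c in calls if c.state != NOCALL]
    if not covs:
        return 0.0
    return float(np.mean(covs)) if rule == "mean" else float(min(covs))


def asm_scan(
    calls_a: Sequence[CpGCall],
    calls_b: Sequence[CpGCall],
    cgis: Sequence[CGIRecord],
    params: ASMParams | None = None,
    phv_positions: Sequence[int] | None = None,
) -> list[ASMRecord]:
    """Score every eligible CGI on both haplotypes and call ASM.

    CGIs with fewer than ``min_cpgs`` CpGs are excluded from the output.
    ``coverage_ok`` requires the aggregated coverage over called sites
    to reach ``min_coverage`` on both haplotypes.  In fixed mode,
    ``is_asm = coverage_ok and abs_diff >= diff_threshold``; in quantile
    mode the threshold is instead the ``top_quantile`` cut on
    ``abs_diff`` among eligible (coverage-passing, defined-score) CGIs,
    taking the ceil(q*n) largest with coordinate-order tie-breaking.

    When ``phv_positions`` (sorted, same chromosome space) is given,
    each record carries the distance from the CGI center to the nearest
    phased variant.
    """
    if params is None:
        params = ASMParams()
    a_by_site: dict[tuple[str, int], CpGCall] = {
        (c.chrom, c.pos): c for c in calls_a
    }
    b_by_site: dict[tuple[str, int], CpGCall] = {
        (c.chrom, c.pos): c for c in calls_b
    }
    phv_arr = (
        np.sort(np.asarray(phv_positions)) if phv_positions is not None else None
    )

    records: list[ASMRecord] = []
    for cgi in sorted(cgis, key=lambda c: (c.chrom, c.start, c.end)):
        if cgi.n_cpg < params.min_cpgs:
            continue
        in_a = [
            c
            for (chrom, pos), c in a_by_site.items()
            if chrom == cgi.chrom and cgi.start <= pos < cgi.end
        ]
        in_b = [
            c
            for (chrom, pos), c in b_by_site.items()
            if chrom == cgi.chrom and cgi.start <= pos < cgi.end
        ]
        score_a = cgi_methylation_score(in_a)
        score_b = cgi_methylation_score(in_b)
        abs_diff = (
            abs(score_a - score_b)
            if not (math.isnan(score_a) or math.isnan(score_b))
            else float("nan")
        )
        coverage_ok = (
            _aggregate_coverage(in_a, params.coverage_rule) >= params.min_coverage
            and _aggregate_coverage(in_b, params.coverage_rule)
            >= params.min_coverage
        )
        if phv_arr is not None and len(phv_arr):
            i = np.searchsorted(phv_arr, cgi.center)
            cands = phv_arr[max(0, i - 1) : i + 1]
            dist = float(np.min(np.abs(cands - cgi.center)))
        else:
            dist = float("inf") if phv_arr is not None else float("nan")
        records.append(
            ASMRecord(
                cgi=cgi,
                score_a=score_a,
                score_b=score_b,
                abs_diff=abs_diff,
                coverage_ok=coverage_ok,
                is_asm=False,
                nearest_phv_distance=dist,
            )
        )

    if params.top_quantile is None:
        return [
            replace(
                r,
                is_asm=bool(
                    r.coverage_ok
                    and not math.isnan(r.abs_diff)
                    and r.abs_diff >= params.diff_threshold
                ),
            )
            for r in records
        ]

    eligible = [
        i
        for i, r in enumerate(records)
        if r.coverage_ok and not math.isnan(r.abs_diff)
    ]
    n_select = math.ceil(params.top_quantile * len(eligible)) if eligible else 0
    # rank by abs_diff descending; ties broken by genomic coordinate
    ranked = sorted(
        eligible,
        key=lambda i: (
            -records[i].abs_diff,
            records[i].cgi.chrom,
            records[i].cgi.start,
        ),
    )
    chosen = set(ranked[:n_select])
    return [
        replace(r, is_asm=(i in chosen)) for i, r in enumerate(records)
    ]


def swap_alleles(records: Sequence[ASMRecord]) -> list[ASMRecord]:
    """Exchange the A and B scores of every record.

    ``abs_diff`` and the ASM verdict are invariant under the swap.
    """
    return [
        replace(r, score_a=r.score_b, score_b=r.score_a) for r in records
    ]


def asm_table(records: Sequence[ASMRecord]) -> pd.DataFrame:
    """Flatten ASM records into a tidy table."""
    return pd.DataFrame(
        [
            {
                "cgi_id": r.cgi.id,
                "chrom": r.cgi.chrom,
                "start": r.cgi.start,
                "end": r.cgi.end,
                "n_cpg": r.cgi.n_cpg,
                "score_a": r.score_a,
                "score_b": r.score_b,
                "abs_diff": r.abs_diff,
                "coverage_ok": r.coverage_ok,
                "is_asm": r.is_asm,
                "nearest_phv_distance": r.nearest_phv_distance,
            }
            for r in records
        ]
    )
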