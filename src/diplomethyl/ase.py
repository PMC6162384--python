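"""Allele-specific expression (ASE) from RNA reads at exonic variants.

Expression from one allele shows up as an imbalance of the two alleles
among RNA reads overlapping an exonic phased heterozygous variant.  This
module tallies reads per allele and tests the split against the
equal-expression null with an exact binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import binomtest

from .haplotyping import PhasedVariant, VariantIndex

__all__ = ["ASECounts", "count_alleles", "imbalance_test", "ase_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ASECounts:
    """Allele read tallies at one exonic phased variant.

    ``count_a``/``count_b`` combine both read classes; the long/short
    breakdown is retained because the two technologies are reported
    separately.  ``imbalance_p`` is None until tested or when no read
    matched either allele.
    """

    phv: PhasedVariant
    gene_id: str | None
    count_a: int
    count_b: int
    count_a_long: int = 0
    count_b_long: int = 0
    count_a_short: int = 0
    count_b_short: int = 0
    n_ignored: int = 0
    imbalance_p: float | None = None


def count_alleles(
    rna_observations: pd.DataFrame,
    variants: VariantIndex,
    gene_of_pos: dict[tuple[str, int], str] | None = None,
    test: bool = True,
    null_ratio: float = 0.5,
) -> list[ASECounts]:
    """Tally RNA reads per allele at each observed phased variant.

    ``rna_observations`` columns: read_id, chrom, pos (0-based), base,
    read_class ("long"/"short").  Bases matching neither allele are
    counted as ignored; observations at positions absent from the
    variant set are skipped with a warning.  When ``test`` is true,
    sites with at least one allele-matching read get an exact binomial
    ``imbalance_p``.
    """
    out: list[ASECounts] = []
    grouped = rna_observations.groupby(["chrom", "pos"], sort=True)
    for (chrom, pos), group in grouped:
        v = variants.get(str(chrom), int(pos))
        if v is None:
            logger.warning(
                "skipping %d RNA observations at %s:%d — no phased variant",
                len(group), chrom, pos,
            )
            continue
        counts = {("a", "long"): 0, ("a", "short"): 0,
                  ("b", "long"): 0, ("b", "short"): 0}
        ignored = 0
        for base, read_class in zip(group["base"], group["read_class"]):
            allele = "a" if base == v.allele_a else "b" if base == v.allele_b else None
            if allele is None:
                ignored += 1
                continue
            cls = read_class if read_class in ("long", "short") else "short"
            counts[(allele, cls)] += 1
        count_a = counts[("a", "long")] + counts[("a", "short")]
        count_b = counts[("b", "long")] + counts[("b", "short")]
        rec = ASECounts(
            phv=v,
            gene_id=(gene_of_pos or {}).get((str(chrom), int(pos))),
            count_a=count_a,
            count_b=count_b,
            count_a_long=counts[("a", "long")],
            count_b_long=counts[("b", "long")],
            count_a_short=counts[("a", "short")],
            count_b_short=counts[("b", "short")],
            n_ignored=ignored,
        )
        if test:
            from dataclasses import replace

            rec = replace(rec, imbalance_p=imbalance_test(rec, null_ratio))
        out.append(rec)
    return out


def imbalance_test(counts: ASECounts, null_ratio: float = 0.5) -> float | None:
    """Two-sided exact binomial p-value for allelic imbalance.

    Tests ``count_a`` successes in ``count_a + count_b`` trials against
    success probability ``null_ratio``.  Returns None when no read
    matched either allele.
    """
    n = counts.count_a + counts.count_b
    if n == 0:
        return None
    return float(binomtest(counts.count_a, n, null_ratio, alternative="two-sided").pvalue)


def ase_table(records: Sequence[ASECounts]) -> pd.DataFrame:
    """Flatten ASE counts into a tidy table."""
    return pd.DataFrame(
        [
            {
                "chrom": r.phv.chrom,
                "pos": r.phv.pos,
                "allele_a": r.phv.allele_a,
                "allele_b": r.phv.allele_b,
                "gene_id": r.gene_id if r.gene_id is not None else "",
                "count_a": r.count_a,
                "count_b": r.count_b,
                "count_a_long": r.count_a_long,
                "count_b_long": r.count_b_long,
                "count_a_short": r.count_a_short,
                "count_b_short": r.count_b_short,
                "n_ignored": r.n_ignored,
                "imbalance_p": r.imbalance_p,
            }
            for r in records
        ]
    )
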