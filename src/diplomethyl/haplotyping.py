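"""Majority-vote assignment of long reads to haplotypes.

Each aligned read is compared against the phased heterozygous SNVs (PHVs)
it spans: a base matching the haplotype-A allele casts an A vote, a base
matching the haplotype-B allele a B vote, and anything else — a missing
base, a deletion, or a substitution to a third base — casts no vote.
The read is assigned to the haplotype with the strict majority; reads
with no informative site or a tied vote are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "PhasedVariant",
    "ReadObservation",
    "HaplotypeCall",
    "VariantIndex",
    "assign_read",
    "assign_readset",
]

#: Sentinel for a PHV position covered by the read span but with no
#: usable base (deleted in the alignment, or simply not reported).
MISSING = "."

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PhasedVariant:
    """A biallelic heterozygous SNV with alleles phased onto haplotypes.

    Positions are 0-based.  ``allele_a`` is the base carried by haplotype
    A, ``allele_b`` by haplotype B.
    """

    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a not in _BASES or self.allele_b not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles must differ at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValueError(f"position must be >= 0, got {self.pos}")


@dataclass
class ReadObservation:
    """One aligned long read reduced to its informative observations.

    ``phv_bases`` maps PHV position -> observed base (or :data:`MISSING`);
    ``cpg_ipd`` maps CpG position (of the plus-strand C) -> IPD-ratio
    values, one per pass covering the site.  Span is 0-based half-open.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    phv_bases: dict[str | int, str] = field(default_factory=dict)
    cpg_ipd: dict[int, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for read "
                f"{self.read_id!r}"
            )
        for pos in list(self.phv_bases) + list(self.cpg_ipd):
            if not self.start <= int(pos) < self.end:
                raise ValueError(
                    f"position {pos} outside span of read {self.read_id!r}"
                )
        for pos, values in self.cpg_ipd.items():
            if any(v <= 0 for v in values):
                raise ValueError(
                    f"IPD ratios must be positive (read {self.read_id!r}, "
                    f"site {pos})"
                )


@dataclass(frozen=True)
class HaplotypeCall:
    """Outcome of majority voting for one read."""

    read_id: str
    verdict: str  # "A", "B" or "UNASSIGNED"
    votes_a: int
    votes_b: int
    n_informative: int


class VariantIndex:
    """Phased variants indexed by (chromosome, position) for O(1) lookup."""

    def __init__(self, variants: Iterable[PhasedVariant]):
        self._by_site: dict[tuple[str, int], PhasedVariant] = {}
        self._by_chrom: dict[str, list[int]] = {}
        for v in variants:
            self._by_site[(v.chrom, v.pos)] = v
            self._by_chrom.setdefault(v.chrom, []).append(v.pos)
        for positions in self._by_chrom.values():
            positions.sort()

    def get(self, chrom: str, pos: int) -> PhasedVariant | None:
        return self._by_site.get((chrom, pos))

    def positions(self, chrom: str) -> list[int]:
        return self._by_chrom.get(chrom, [])

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def __len__(self) -> int:
        return len(self._by_site)

    def __iter__(self):
        return iter(self._by_site.values())


def assign_read(read: ReadObservation, variants: VariantIndex) -> HaplotypeCall:
    """Assign one read to haplotype A or B by majority vote over its PHVs.

    Votes are unweighted.  A read whose chromosome carries no indexed
    variants, or whose observed bases never match either allele, has zero
    informative sites and is unassigned; so is a read with a tied vote.
    """
    votes_a = votes_b = 0
    for pos, base in read.phv_bases.items():
        variant = variants.get(read.chrom, int(pos))
        if variant is None or base == MISSING:
            continue
        if base == variant.allele_a:
            votes_a += 1
        elif base == variant.allele_b:
            votes_b += 1
        # third-base substitutions cast no vote
    if votes_a > votes_b:
        verdict = "A"
    elif votes_b > votes_a:
        verdict = "B"
    else:
        verdict = "UNASSIGNED"
    return HaplotypeCall(
        read_id=read.read_id,
        verdict=verdict,
        votes_a=votes_a,
        votes_b=votes_b,
        n_informative=votes_a + votes_b,
    )


def assign_readset(
    reads: Sequence[ReadObservation], variants: VariantIndex
) -> tuple[pd.DataFrame, dict]:
    """Assign every read and summarize the assignment outcome.

    Returns
    -------
    calls :
        One row per read: ``read_id, verdict, votes_a, votes_b,
        n_informative, length``.  Row order follows a stable sort by
        ``read_id`` so the output is independent of input order.
    summary :
        Counts and fractions of assigned reads, mean read length of
        assigned vs all reads, and the distribution of the number of
        informative sites per read.
    """
    records = []
    for read in reads:
        call = assign_read(read, variants)
        records.append(
            {
                "read_id": call.read_id,
                "verdict": call.verdict,
                "votes_a": call.votes_a,
                "votes_b": call.votes_b,
                "n_informative": call.n_informative,
                "length": read.end - read.start,
            }
        )
    calls = pd.DataFrame(
        records,
        columns=[
            "read_id", "verdict", "votes_a", "votes_b", "n_informative",
            "length",
        ],
    )
    if len(calls):
        calls = calls.sort_values("read_id", kind="stable").reset_index(drop=True)

    n_total = len(calls)
    assigned = calls[calls["verdict"] != "UNASSIGNED"] if n_total else calls
    n_assigned = len(assigned)
    summary = {
        "n_reads": n_total,
        "n_assigned": n_assigned,
        "n_unassigned": n_total - n_assigned,
        "fraction_assigned": (n_assigned / n_total) if n_total else 0.0,
        "mean_length_all": float(calls["length"].mean()) if n_total else 0.0,
        "mean_length_assigned": (
            float(assigned["length"].mean()) if n_assigned else 0.0
        ),
        "n_informative_distribution": (
            calls["n_informative"].value_counts().sort_index().to_dict()
            if n_total
            else {}
        ),
    }
    return calls, summary
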