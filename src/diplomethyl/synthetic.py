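"""Synthetic diploid datasets with known truth.

Two generators cover the package's needs:

* :func:`simulate_methylation_dataset` — per-CpG IPD-ratio values for the
  two haplotypes of a diploid with planted methylation states and a
  chosen fraction of allele-specifically methylated (ASM) CpG islands.
  This is the substrate of the methylation-calling and perturbation
  experiments.
* :func:`simulate` — a full pipeline dataset from a
  :class:`SimulationSpec`: phased variants, CpG islands, a simple gene
  model, long-read observations with the platform error profile applied
  at variant sites, RNA allele observations at exonic variants, and
  truth tables for every level.

All randomness flows from one seed through ``numpy.random.default_rng``;
identical spec + seed gives identical output.

The read simulator applies the per-site three-outcome model at each
covered phased variant: support-correct (own allele), support-wrong
(the other haplotype's allele, probability substitution_rate/3), or
miss (deleted, or substituted to a base matching neither allele).
Insertions are not materialized in observation records — they fall
between bases and cannot affect a variant-site vote — their rate is
honoured only in the error-model bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .error_model import DEFAULT_ERROR_PROFILE, ErrorProfile
from .haplotyping import MISSING, PhasedVariant, ReadObservation
from .methylation import METHYLATED, UNMETHYLATED, CpGCall, CpGSiteSummary

__all__ = [
    "SimulationSpec",
    "TruthTables",
    "MethylationDataset",
    "SimulatedDataset",
    "simulate",
    "simulate_methylation_dataset",
    "simulate_assignment_outcomes",
    "regression_fixture",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# per-CpG IPD dataset (methylation calling / perturbation substrate)
# ---------------------------------------------------------------------------


@dataclass
class MethylationDataset:
    """Per-CpG IPD values for both haplotypes with planted truth states.

    ``sites`` lists (chrom, pos) in order; ``ipd_values[hap][i]`` is the
    array of per-read IPD ratios at site i for that haplotype;
    ``truth_states[hap][i]`` the generating state; ``cgi_ids[i]`` the
    island each site belongs to.
    """

    sites: list[tuple[str, int]]
    ipd_values: dict[str, list[np.ndarray]]
    truth_states: dict[str, list[str]]
    cgi_ids: list[int]

    def with_values(self, values: dict[str, list[np.ndarray]]) -> "MethylationDataset":
        return MethylationDataset(
            sites=self.sites,
            ipd_values=values,
            truth_states=self.truth_states,
            cgi_ids=self.cgi_ids,
        )

    def site_summaries(self, haplotype: str) -> list[CpGSiteSummary]:
        out = []
        for (chrom, pos), values in zip(self.sites, self.ipd_values[haplotype]):
            # non-positive values (possible under extreme perturbation of
            # below-1 ratios) are unusable, same rule as summarize_ipd
            usable = np.asarray(values)
            usable = usable[usable > 0]
            n = len(usable)
            out.append(
                CpGSiteSummary(
                    chrom=chrom,
                    pos=pos,
                    haplotype=haplotype,
                    coverage=n,
                    mean_log_ipd=float(np.mean(np.log(usable))) if n else float("nan"),
                )
            )
        return out

    def truth_calls(self) -> list[CpGCall]:
        calls = []
        for hap in sorted(self.ipd_values):
            for (chrom, pos), state, values in zip(
                self.sites, self.truth_states[hap], self.ipd_values[hap]
            ):
                calls.append(
                    CpGCall(
                        chrom=chrom,
                        pos=pos,
                        haplotype=hap,
                        state=state,
                        coverage=len(values),
                    )
                )
        return calls


def simulate_methylation_dataset(
    n_cgi: int = 200,
    cpg_per_cgi: int = 50,
    coverage: int = 20,
    asm_fraction: float = 0.5,
    mu_meth: float = math.log(1.3),
    mu_unmeth: float = 0.0,
    sigma: float = 0.6,
    cpg_spacing: int = 20,
    seed: int = 42,
) -> MethylationDataset:
    """Generate planted-truth IPD data over ``n_cgi`` islands.

    Each island carries ``cpg_per_cgi`` CpGs; every CpG receives exactly
    ``coverage`` IPD-ratio values per haplotype, lognormal with log-mean
    ``mu_meth`` or ``mu_unmeth`` according to the island's planted state
    and log-sd ``sigma``.  A fraction ``asm_fraction`` of islands is ASM
    (one haplotype methylated, the other not, orientation random); the
    rest share one state on both haplotypes, methylated or unmethylated
    with equal probability.
    """
    if not 0.0 <= asm_fraction <= 1.0:
        raise ValueError("asm_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_asm = int(round(asm_fraction * n_cgi))
    is_asm = np.zeros(n_cgi, dtype=bool)
    is_asm[rng.choice(n_cgi, size=n_asm, replace=False)] = True

    sites: list[tuple[str, int]] = []
    cgi_ids: list[int] = []
    values: dict[str, list[np.ndarray]] = {"A": [], "B": []}
    truth: dict[str, list[str]] = {"A": [], "B": []}
    pos = 1000
    for cgi in range(n_cgi):
        if is_asm[cgi]:
            state_a = METHYLATED if rng.random() < 0.5 else UNMETHYLATED
            state_b = UNMETHYLATED if state_a == METHYLATED else METHYLATED
        else:
            state_a = state_b = METHYLATED if rng.random() < 0.5 else UNMETHYLATED
        for _ in range(cpg_per_cgi):
            sites.append(("chr1", pos))
            cgi_ids.append(cgi)
            for hap, state in (("A", state_a), ("B", state_b)):
                mu = mu_meth if state == METHYLATED else mu_unmeth
                values[hap].append(np.exp(rng.normal(mu, sigma, size=coverage)))
                truth[hap].append(state)
            pos += cpg_spacing
        pos += 2000  # gap between islands
    return MethylationDataset(
        sites=sites, ipd_values=values, truth_states=truth, cgi_ids=cgi_ids
    )


# ---------------------------------------------------------------------------
# per-site vote outcome simulation (error-model Monte Carlo)
# ---------------------------------------------------------------------------


def simulate_assignment_outcomes(
    n_reads: int,
    n_snvs: int,
    profile: ErrorProfile = DEFAULT_ERROR_PROFILE,
    seed: int = 0,
) -> dict[str, int]:
    """Monte-Carlo the majority vote for ``n_reads`` reads of ``n_snvs`` sites.

    Draws per-site outcomes from the three-way model and tallies reads
    by vote result.  Returns counts for keys ``wrong``, ``unassigned``
    and ``correct``; the empirical fractions converge on
    :func:`~diplomethyl.error_model.exact_outcome_distribution`.
    """
    if n_reads < 1 or n_snvs < 1:
        raise ValueError("n_reads and n_snvs must be >= 1")
    rng = np.random.default_rng(seed)
    p = [profile.p_support_correct, profile.p_support_wrong, profile.p_miss]
    # outcome codes: 0 correct, 1 wrong, 2 miss
    draws = rng.choice(3, size=(n_reads, n_snvs), p=p)
    votes_correct = (draws == 0).sum(axis=1)
    votes_wrong = (draws == 1).sum(axis=1)
    wrong = int((votes_wrong > votes_correct).sum())
    unassigned = int((votes_wrong == votes_correct).sum())
    return {
        "wrong": wrong,
        "unassigned": unassigned,
        "correct": n_reads - wrong - unassigned,
    }


# ---------------------------------------------------------------------------
# full pipeline dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a full synthetic diploid dataset.

    Defaults mirror the long-read study regime: ~8 kb reads, 20-fold
    per-haplotype coverage (comfortably above the 16-fold calling floor),
    the 10%/5%/3% insertion/deletion/substitution error profile, and the
    lognormal IPD-signal parameters of the methylation caller.
    """

    genome_length: int = 200_000
    n_phv: int = 200
    phv_placement: str = "uniform"  # or "clustered"
    n_cgi: int = 10
    cpg_per_cgi: tuple[int, int] = (30, 60)
    asm_fraction: float = 0.3
    read_length_mean: float = 8000.0
    read_length_sd: float = 2000.0
    coverage_per_haplotype: float = 20.0
    error_profile: ErrorProfile = DEFAULT_ERROR_PROFILE
    mu_meth: float = math.log(1.3)
    mu_unmeth: float = 0.0
    sigma: float = 0.6
    n_genes: int = 4
    exons_per_gene: int = 3
    rna_reads_per_phv: int = 30
    imprinted_gene_fraction: float = 0.5
    seed: int = 42
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_phv <= 0 or self.n_cgi <= 0:
            raise ValueError("genome_length, n_phv and n_cgi must be positive")
        if not 0.0 <= self.asm_fraction <= 1.0:
            raise ValueError("asm_fraction must be in [0, 1]")
        if self.coverage_per_haplotype <= 0:
            raise ValueError("coverage_per_haplotype must be positive")
        if self.phv_placement not in ("uniform", "clustered"):
            raise ValueError(f"unknown phv_placement {self.phv_placement!r}")
        # feasibility: islands (with spacing) must fit in the genome
        max_cgi_len = self.cpg_per_cgi[1] * 20
        if self.n_cgi * (max_cgi_len + 200) > self.genome_length:
            raise ValueError("CGIs do not fit in the genome length")


@dataclass
class TruthTables:
    """Ground truth underlying a :class:`SimulatedDataset`."""

    read_haplotypes: pd.DataFrame  # read_id, true_haplotype
    cpg_states: pd.DataFrame  # chrom, pos, haplotype, state
    cgi_asm: pd.DataFrame  # cgi_id, chrom, start, end, n_cpg, is_asm
    gene_ratios: pd.DataFrame  # gene_id, allele_a_fraction


@dataclass
class SimulatedDataset:
    """In-memory synthetic dataset; ``write`` emits the standard files."""

    spec: SimulationSpec
    variants: list[PhasedVariant]
    cgis: pd.DataFrame  # chrom, start, end, n_cpg, cgi_id
    cpg_positions: list[int]
    genes: pd.DataFrame  # gene_id, start, end
    exons: pd.DataFrame  # gene_id, start, end
    reads: list[ReadObservation]
    rna_observations: pd.DataFrame  # read_id, chrom, pos, base, read_class
    truth: TruthTables

    def write(self, out_dir) -> dict[str, str]:
        """Write VCF / BED / GFF3 / TSV files; returns name -> path."""
        from . import io as dio

        return dio.write_dataset(self, out_dir)


def _place_cgis(spec: SimulationSpec, rng: np.random.Generator):
    """Evenly slotted, non-overlapping islands with 20 bp CpG spacing."""
    slot = spec.genome_length // spec.n_cgi
    lo, hi = spec.cpg_per_cgi
    cgis, cpgs, cgi_of_cpg = [], [], []
    for i in range(spec.n_cgi):
        n_cpg = int(rng.integers(lo, hi + 1))
        start = i * slot + 100
        positions = [start + 20 * j for j in range(n_cpg)]
        end = positions[-1] + 2
        cgis.append((spec.chrom, start, end, n_cpg, f"CGI_{i:04d}"))
        cpgs.extend(positions)
        cgi_of_cpg.extend([i] * n_cpg)
    df = pd.DataFrame(cgis, columns=["chrom", "start", "end", "n_cpg", "cgi_id"])
    return df, cpgs, cgi_of_cpg


def _place_phvs(spec: SimulationSpec, rng: np.random.Generator):
    n = spec.n_phv
    if spec.phv_placement == "uniform":
        positions = rng.choice(spec.genome_length, size=n, replace=False)
    else:
        n_clusters = max(1, n // 20)
        centers = rng.choice(spec.genome_length, size=n_clusters, replace=False)
        positions = np.unique(
            np.clip(
                rng.normal(
                    centers[rng.integers(0, n_clusters, size=2 * n)], 500.0
                ).astype(int),
                0,
                spec.genome_length - 1,
            )
        )
        positions = rng.choice(positions, size=min(n, len(positions)), replace=False)
    positions = np.sort(positions)
    variants = []
    for pos in positions:
        a, b = rng.choice(4, size=2, replace=False)
        variants.append(
            PhasedVariant(
                chrom=spec.chrom,
                pos=int(pos),
                allele_a=str(_BASES[a]),
                allele_b=str(_BASES[b]),
            )
        )
    return variants


def _place_genes(spec: SimulationSpec, rng: np.random.Generator):
    """Non-overlapping genes, each with evenly spaced exons."""
    genes, exons = [], []
    slot = spec.genome_length // max(spec.n_genes, 1)
    for g in range(spec.n_genes):
        gene_len = int(0.5 * slot)
        start = g * slot + slot // 4
        end = start + gene_len
        gid = f"GENE_{g:03d}"
        genes.append((gid, start, end))
        exon_len = gene_len // (2 * spec.exons_per_gene)
        for e in range(spec.exons_per_gene):
            ex_start = start + e * 2 * exon_len
            exons.append((gid, ex_start, ex_start + exon_len))
    return (
        pd.DataFrame(genes, columns=["gene_id", "start", "end"]),
        pd.DataFrame(exons, columns=["gene_id", "start", "end"]),
    )


def _simulate_reads(
    spec: SimulationSpec,
    variants: list[PhasedVariant],
    cpg_positions: list[int],
    cpg_states: dict[str, list[str]],
    rng: np.random.Generator,
):
    """Sample reads per haplotype; apply the error model at PHV sites."""
    profile = spec.error_profile
    p_wrong = profile.p_support_wrong
    p_miss = profile.p_miss
    p_correct = profile.p_support_correct
    # within a miss, a deletion leaves MISSING, an off-allele substitution
    # leaves a visible third base
    p_del_given_miss = (
        profile.deletion_rate / p_miss if p_miss > 0 else 0.0
    )
    phv_pos = np.array([v.pos for v in variants])
    cpg_pos = np.array(cpg_positions)
    n_reads = int(
        round(
            spec.coverage_per_haplotype
            * spec.genome_length
            / spec.read_length_mean
        )
    )
    reads, read_truth = [], []
    counter = 0
    for hap in ("A", "B"):
        lengths = np.clip(
            rng.normal(spec.read_length_mean, spec.read_length_sd, size=n_reads),
            200,
            spec.genome_length,
        ).astype(int)
        starts = rng.integers(0, np.maximum(spec.genome_length - lengths, 1))
        for length, start in zip(lengths, starts):
            start = int(start)
            end = int(start + length)
            read_id = f"read_{counter:07d}"
            counter += 1
            phv_bases: dict[int, str] = {}
            lo, hi = np.searchsorted(phv_pos, [start, end])
            for idx in range(lo, hi):
                v = variants[idx]
                own = v.allele_a if hap == "A" else v.allele_b
                other = v.allele_b if hap == "A" else v.allele_a
                u = rng.random()
                if u < p_correct:
                    phv_bases[v.pos] = own
                elif u < p_correct + p_wrong:
                    phv_bases[v.pos] = other
                else:
                    if rng.random() < p_del_given_miss:
                        phv_bases[v.pos] = MISSING
                    else:
                        third = [b for b in "ACGT" if b not in (own, other)]
                        phv_bases[v.pos] = third[rng.integers(0, len(third))]
            cpg_ipd: dict[int, list[float]] = {}
            lo, hi = np.searchsorted(cpg_pos, [start, end])
            for idx in range(lo, hi):
                state = cpg_states[hap][idx]
                mu = spec.mu_meth if state == METHYLATED else spec.mu_unmeth
                cpg_ipd[int(cpg_pos[idx])] = [
                    float(np.exp(rng.normal(mu, spec.sigma)))
                ]
            reads.append(
                ReadObservation(
                    read_id=read_id,
                    chrom=spec.chrom,
                    start=start,
                    end=end,
                    phv_bases=phv_bases,
                    cpg_ipd=cpg_ipd,
                )
            )
            read_truth.append((read_id, hap))
    return reads, pd.DataFrame(read_truth, columns=["read_id", "true_haplotype"])


def _simulate_rna(
    spec: SimulationSpec,
    variants: list[PhasedVariant],
    exons: pd.DataFrame,
    rng: np.random.Generator,
):
    """RNA allele observations at exonic PHVs with per-gene allelic ratios."""
    gene_ids = sorted(exons["gene_id"].unique())
    ratios = {}
    for gid in gene_ids:
        if rng.random() < spec.imprinted_gene_fraction:
            # monoallelic: expressed allele chosen at random
            ratios[gid] = 1.0 if rng.random() < 0.5 else 0.0
        else:
            ratios[gid] = 0.5
    rows = []
    counter = 0
    for v in variants:
        hit = exons[(exons["start"] <= v.pos) & (v.pos < exons["end"])]
        if hit.empty:
            continue
        gid = hit.iloc[0]["gene_id"]
        frac_a = ratios[gid]
        for _ in range(spec.rna_reads_per_phv):
            base = v.allele_a if rng.random() < frac_a else v.allele_b
            read_class = "long" if rng.random() < 0.1 else "short"
            rows.append((f"rna_{counter:07d}", spec.chrom, v.pos, base, read_class))
            counter += 1
    obs = pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos", "base", "read_class"]
    )
    gene_ratios = pd.DataFrame(
        sorted(ratios.items()), columns=["gene_id", "allele_a_fraction"]
    )
    return obs, gene_ratios


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a complete synthetic diploid dataset from ``spec``.

    Island methylation truth follows the same scheme as
    :func:`simulate_methylation_dataset`: ASM islands have opposite
    states on the two haplotypes, others share one state.
    """
    rng = np.random.default_rng(spec.seed)
    cgis, cpg_positions, cgi_of_cpg = _place_cgis(spec, rng)
    variants = _place_phvs(spec, rng)
    genes, exons = _place_genes(spec, rng)

    n_cgi = len(cgis)
    n_asm = int(round(spec.asm_fraction * n_cgi))
    is_asm = np.zeros(n_cgi, dtype=bool)
    is_asm[rng.choice(n_cgi, size=n_asm, replace=False)] = True
    state_a_by_cgi, state_b_by_cgi = [], []
    for i in range(n_cgi):
        if is_asm[i]:
            sa = METHYLATED if rng.random() < 0.5 else UNMETHYLATED
            sb = UNMETHYLATED if sa == METHYLATED else METHYLATED
        else:
            sa = sb = METHYLATED if rng.random() < 0.5 else UNMETHYLATED
        state_a_by_cgi.append(sa)
        state_b_by_cgi.append(sb)
    cpg_states = {
        "A": [state_a_by_cgi[c] for c in cgi_of_cpg],
        "B": [state_b_by_cgi[c] for c in cgi_of_cpg],
    }

    reads, read_truth = _simulate_reads(
        spec, variants, cpg_positions, cpg_states, rng
    )
    rna_obs, gene_ratios = _simulate_rna(spec, variants, exons, rng)

    cpg_truth = pd.DataFrame(
        [
            (spec.chrom, pos, hap, cpg_states[hap][i])
            for hap in ("A", "B")
            for i, pos in enumerate(cpg_positions)
        ],
        columns=["chrom", "pos", "haplotype", "state"],
    )
    cgi_truth = cgis.copy()
    cgi_truth["is_asm"] = is_asm
    truth = TruthTables(
        read_haplotypes=read_truth,
        cpg_states=cpg_truth,
        cgi_asm=cgi_truth[["cgi_id", "chrom", "start", "end", "n_cpg", "is_asm"]],
        gene_ratios=gene_ratios,
    )
    return SimulatedDataset(
        spec=spec,
        variants=variants,
        cgis=cgis,
        cpg_positions=cpg_positions,
        genes=genes,
        exons=exons,
        reads=reads,
        rna_observations=rna_obs,
        truth=truth,
    )


#: Registry of named miniature datasets for regression testing.
_FIXTURES: dict[str, SimulationSpec] = {
    "mini-diploid": SimulationSpec(
        genome_length=100_000,
        n_phv=200,
        n_cgi=10,
        cpg_per_cgi=(30, 50),
        asm_fraction=0.3,
        coverage_per_haplotype=20.0,
        seed=42,
    ),
}


def regression_fixture(name: str) -> SimulatedDataset:
    """Return a small frozen dataset from the fixture registry.

    The dataset is regenerated deterministically from its registered
    spec, so repeated calls are identical.
    """
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return simulate(spec)
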