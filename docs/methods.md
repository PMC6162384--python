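# Methods

## Read-assignment error model

A long read is assigned to haplotype A or B by unweighted majority vote
over the phased heterozygous SNVs (PHVs) it covers. Sequencing errors act
per site through three mutually exclusive outcomes:

| outcome | probability (profile ins/del/sub) | default (0.10/0.05/0.03) |
|---|---|---|
| support wrong allele | sub/3 | 0.01 |
| no vote (miss) | del + (2/3)·sub | 0.07 |
| support correct allele | 1 − del − sub | 0.92 |

Substitution to the other haplotype's base is one of three equally likely
wrong bases, hence sub/3. A deleted base or a substitution to a base
matching neither allele leaves the site uninformative. Insertions occur
between template bases and cannot change the base observed at a variant
site; the insertion rate is carried in the profile for completeness but
does not enter the vote model.

The closed form sums over the number of missed sites *k* the probability
that a **strict majority** of the remaining *N − k* sites support the
wrong allele, with the inner summation index starting at
⌊(N−k)/2⌋ + 1. Two deliberate choices:

1. **Strict majority, ties unassigned.** Counting ties as errors (an inner
   bound of ⌈(N−k)/2⌉) would give ≈2.15% at N = 2 rather than the correct
   0.15%, and is inconsistent with the assignment rule, which discards
   tied reads rather than assigning them. The strict-majority form
   reproduces 1%, 0.15%, 0.047% and 0.010% at N = 1..4.
2. **Dropped support-correct factor.** The closed form omits the
   (1 − del − sub)^(N−k−l) factor on the sites that vote correctly, so it
   upper-bounds the exact misassignment probability; equality holds for
   N ≤ 2 (no free site remains in the dominant terms). The exhaustive
   oracle `exact_outcome_distribution` enumerates the three-outcome
   compositions with multinomial weights (mathematically identical to
   enumerating all 3^N outcome vectors) and gives 4.45×10⁻⁴ at N = 3
   versus the closed form's 4.69×10⁻⁴.

All rates live in one `ErrorProfile` object; nothing is hard-coded in the
formulas.

## Regional methylation calling

5mC perturbs SMRT polymerase kinetics weakly at single-molecule level, so
per-CpG, per-haplotype calls pool evidence two ways: across reads (the
mean natural-log IPD ratio, weighted by coverage in the likelihood) and
along the genome (two-state segmentation). The caller minimizes

    Σ_i cov_i (x_i − μ_state(i))² / (2σ²) + γ · #switches

exactly, by dynamic programming over the two states with suffix optima and
a forward greedy pass.

Parameters (natural-log units):

* `mu_meth = ln 1.3` — methylated CpGs slow incorporation by ~30% on
  average; `mu_unmeth = 0` (ratio 1 to the unmodified expectation).
* `sigma = 0.6` — per-measurement noise chosen so a single read cannot
  separate the states (d ≈ 0.44σ) and regional pooling is genuinely
  required, mirroring the character of real SMRT 5mC signal.
* `switch_penalty γ = 3.0` — a state flip must be supported by roughly
  two clearly contrary sites (a site at the opposite mean contributes
  ≈1.9 cost units at 20×); this sets segment granularity.
* `min_coverage = 16` per haplotype — sites below it are NOCALL, excluded
  from the state sequence entirely so they never influence neighbours
  (sites flanking a NOCALL gap are treated as adjacent).

Tie-breaking is deterministic: among equal-cost labelings prefer fewer
switches, then the unmethylated state at the first differing site. Costs
are compared as (cost, switches) pairs inside the DP — lexicographic order
is preserved by componentwise addition, so the DP optimum carries the
minimum switch count among minimum-cost labelings. With γ = 0 the caller
reduces to per-site nearest-mean classification. Both-strand IPD
measurements are pooled at the plus-strand C coordinate; per-read subread
values are averaged into the site summary.

This two-state Gaussian fused segmentation is this package's own regional
caller. It preserves the regional character and coverage requirement of
linear-discriminant segmentation callers used on real SMRT data while
being fully specified here; it makes no claim to reproduce any published
caller's coefficients, and it does not attempt single-molecule calls or
non-CpG modifications.

## Perturbation analysis

Misassigned reads contaminate the other haplotype's IPD pool. The effect
is emulated by perturbing **every stored per-read IPD value
independently** before summarization:

    IPD' = IPD + u · P · (IPD − 1),  u ~ Uniform[−1, 1]

with *P* the assignment-error probability (default 0.01). The uniform law
reflects ignorance of the true allelic contrast: the perturbation is fully
realized only when the alleles are completely contrastive. The
transformation never changes the sign of IPD − 1; under extreme settings
(P near 1 with ratios below ½) it can produce non-positive values, which
are discarded at summarization like any other unusable measurement.
Applying the perturbation per value rather than to site-level aggregates
is the stricter reading of per-position independence; the experiment
reports sensitivity and precision of unmethylated calls before and after.

## ASM and ASE calling

A CpG island's per-haplotype score is the unweighted mean of its binary
CpG states over called sites (NaN when every site is NOCALL). Filters:

* **island size** ≥ 30 CpGs — smaller islands are excluded before scoring;
* **coverage** — mean coverage over the island's called sites must reach
  16× on *both* haplotypes. The mean (rather than min or every-site) was
  chosen for robustness to single-site dropouts; `coverage_rule="min"` is
  available for the stricter reading.
* **threshold** — |score_A − score_B| ≥ 0.68 in fixed mode. Because that
  cutoff is sample-derived (the top-1% quantile in the reference sample),
  a quantile mode recomputes it on the data at hand, taking the
  ⌈q·n⌉ largest differences with coordinate-order tie-breaking.

Island-to-variant distance is measured from the integer island center.
ASE is the operational definition — allele imbalance of RNA reads at
exonic PHVs — tested with an exact two-sided binomial test against a
50/50 null. Long- and short-read counts are tallied separately and
combined. Gene/isoform-level hierarchical ASE models and mapping-bias
correction are out of scope.

PHV genic context uses exon > intron > intergenic precedence across
overlapping transcripts (a variant usable for ASE must be exonic in at
least one transcript); category lengths for the per-kbp densities are
computed on merged intervals.

## Synthetic data

The generator defines the package's study conditions and every truth
table the tests score against.

* **Error profile** 10% insertion / 5% deletion / 3% substitution.
  Misses split into deletions (leaving no base) and off-allele
  substitutions (leaving a visible third base) in their natural ratio
  5:2, exercising both no-vote paths. Insertions are not materialized in
  observation records — they cannot affect a variant-site vote.
* **IPD signal** lognormal per value: log-mean ln 1.3 (methylated) or 0
  (unmethylated), log-sd 0.6.
* **Methylation truth** per island: an ASM island is fully contrastive
  (one haplotype methylated, the other not, orientation random); other
  islands share one state, methylated or unmethylated with equal
  probability.
* **Reads** ~8 kb normal lengths (sd 2 kb, floor 200 bp), uniform starts,
  20× per haplotype by default — comfortably above the 16× calling floor.
* **RNA observations** are generated only at exonic PHVs, error-free,
  with per-gene allele-A fractions of 1.0/0.0 (imprinted-like) or 0.5
  (biallelic).
* The default calling experiment uses 200 islands × 50 CpGs at 20× per
  haplotype with half the islands ASM, seed 42 — large enough that
  sensitivity/precision estimates have ~0.2% Monte-Carlo error yet runs
  in seconds.

What the generator does **not** emulate: sequence-level errors outside
variant sites (alignment is consumed, not simulated), position- or
context-dependent error rates, phasing errors in the variant input
(which would bias, not randomize, assignment), subread-count variation in
kinetics, and partially methylated (intermediate) islands. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under the stated signal model, not performance on real
flowcell data.

## Numerical and interface conventions

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted exactly once at the reading boundary, and the haplotype-A
allele is the one on the first phase strand (0|1 ⇒ A = REF). Multi-allelic,
indel and unphased records are skipped with counted warnings. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
one seed yields one reproducible stream, and identical spec + seed
produce byte-identical simulation output. Floats in the observation TSV
use shortest-exact representation so write-then-read round-trips are
lossless. The exhaustive outcome oracle is capped at N = 15 by contract;
the closed form has no practical limit.
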