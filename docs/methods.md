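# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want to know.  It states no
empirical claim that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and containers

All internal coordinates are 1-based inclusive; the only conversion to
0-based half-open BED happens in `io_formats.write_regions_bed`
(`start_bed = start − 1`).  The `HaplotypePanel` holds phased haplotypes
as a `(2·n_samples) × n_sites` int8 matrix polarized to an explicit
ancestral allele (0 ancestral, 1 derived, −1 missing).  The ancestral
state is always an input (an `AA` tag or a position→allele table), never
inferred from frequency.  Missing alleles are excluded from frequency
denominators rather than imputed — the simplest treatment consistent
with the ingestion filter (biallelic SNPs, per-site missing rate ≤ 5%).

## Selection statistics

**FST.**  The per-site Hudson estimator in the Bhatia form,
`[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂)+p₂(1−p₁)]`,
chosen because it is unbiased under unequal sample sizes (54 vs 74
diploids) and is the standard input to per-SNP PBS scans.  Negative
estimates are clamped to 0 and the upper end to `1 − ε` (ε = 10⁻⁶) so
that `T = −ln(1−FST)` stays finite and non-negative at fixed
differences.  Sites fixed for the same allele in both populations are
flagged missing.

**PBS** = `(T_TR + T_TO − T_RO)/2` for target T, reference R, outgroup O.
Negative PBS is retained (it is informative about selection in the other
branches).  The two scan directions swap the target and reference roles.

**EHH / XP-EHH.**  EHH at marker distance k is the probability that two
haplotypes sampled without replacement from the population sample are
identical at every marker between the core (exclusive) and k:
`Σ_h C(m_h,2) / C(m,2)`.  iHH is the trapezoidal integral of EHH over
*physical* distance, both directions, truncated at the first marker where
EHH < 0.05 (that marker's trapezoid is included), stopping at inter-
marker gaps > 200 kb or the edge of the data.  Physical rather than
genetic distance because a recombination map is an external input that
synthetic data cannot supply; the cutoff and gap rule live in
`XPEHHConfig` for sensitivity analyses.  Raw XP-EHH is
`ln(iHH_target/iHH_ref)` and is z-normalized over all scored sites;
positive normalized scores support selection in the target.  The
implementation tracks pairwise first-mismatch positions with bit-packed
XOR arithmetic (32 markers per 64-bit word); a naive haplotype-grouping
implementation is kept in the test suite as its oracle.  Missing alleles
are treated as a third allelic symbol (two haplotypes missing at the
same marker still match each other).

**D statistic.**  Per-site `ABBA = (1−p_W)p_X p_Y(1−p_Z)`,
`BABA = p_W(1−p_X)p_Y(1−p_Z)`, `D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`, with a
delete-one block jackknife (default 100-SNP blocks) for the Z score.

## Windowed scan

Sliding windows of 20 SNPs with step 5 (missing-score SNPs removed before
indexing; a trailing remainder < 20 SNPs yields no window).  Window PBS =
mean of the 20 per-SNP values; window XP-EHH = max.  Window- (PBS,
Fisher) or SNP-level (XP-EHH) units at or above the empirical 99th
percentile merge when ≤ 10 kb apart (gap measured between nearest
endpoints, 10 kb inclusive); region score = top member unit.  The Fisher
score is `−log10(rank_PBS) − log10(rank_XPEHH)` with upper-tail
percentile ranks, ties counted as ≥ (the conservative direction; ranks
are bounded below by 1/N so the score is finite, and the combination
depends on the inputs only through ranks).  The lower-tail XP-EHH scan
(selection in the reference population) negates the track so one code
path always works on the upper tail.

Resampling significance for a region draws M score units uniformly *with
replacement* and reports the add-one estimator `(1+k)/(1+M)`, which can
never return 0.  Final regions: per method, the top 10 by score passing
that method's p threshold, extended by ±50 kb (clipped to the
chromosome), unioned on ≥ 1 bp overlap with method provenance retained;
the merge is idempotent.

**Thresholds at desk scale.**  The genome-scale defaults (2·10⁻⁵ XP-EHH,
2·10⁻⁴ PBS, 2·10⁻³ Fisher) assume millions of score units; with
replacement-resampling the achievable p is floored near 1/N_units, so on
a 5,000-SNP synthetic track they are unreachable by construction.  The
demo configuration (`pipeline.demo_scan_config`) therefore sets each
method's cutoff to admit roughly the ten best-supported units
(`10/N_units`), preserving the genome-scale intent — "a handful of
extreme units genome-wide" — in rank terms.  The calibration of the
resampling p itself is checked against exact exceedance counts.

## Trajectory likelihood and candidate ranking

The genealogy-based trajectory likelihood used in this kind of study is
replaced by a discretized Wright–Fisher model that preserves its
interface (a non-negative per-SNP logLR with stochastic replicates): the
allele frequency lives on B = 100 bins over (0,1) (midpoint grid); per
generation it moves by `Normal(x + s·x(1−x), x(1−x)/(2Nₑ))`, bin-
integrated, with the two near-boundary bins absorbing; the initial
distribution is uniform; the only data enter as a `Binomial(n, x)`
emission of the present-day derived count at the final generation
(G = 980, Nₑ = 10⁴ by default; s on {0, 0.002, …, 0.1}, positive
selection only).  Because the transition kernel does not depend on the
data, the final-generation state distribution is pre-computed once per s
(matrix binary exponentiation) and each logLR evaluation is a dot
product, which is what makes the five-plus-fifty-run ranking procedure
cheap.  Run-to-run stochasticity comes from bootstrap resampling of the
n sampled chromosomes (resampled count ~ Binomial(n, k/n), retried up to
10 times if monomorphic, then flagged unscorable).

Ranking per region: eligible SNPs (DAF ≥ 0.05, segregating) are scored 5
times and averaged; the top five get 50 additional runs; the winner is
the highest 50-run mean, ties broken to the lower position so the
procedure is deterministic given the seed schedule.

**Known limitation (by construction).**  A likelihood that observes only
the present-day count is monotone in that count, so the ranking reduces
to frequency ordering plus bootstrap noise.  In a hard sweep, any allele
that was already common on the sweep background rises *above* the swept
allele's frequency (f·c + (1−f·c)·q > f for background frequency q > 0),
so such hitchhikers — not the focal SNP — top the ranking whenever they
exist, which on any realistic site-frequency spectrum is essentially
always.  Distinguishing them requires trajectory (genealogical)
information this stand-in deliberately does not use.  The acceptance
suite measures this honestly: region-level recovery of the sweep is
≥ 90%, focal-SNP recovery by ranking is near 0 and its acceptance test
is expected to fail.  Separately, the transition kernel itself is
validated by maximum-likelihood recovery of s from fully observed
forward-simulated trajectories (`fit_s_from_trajectory`, 200-bin grid):
under (s = 0.05, Nₑ = 10⁴, G = 980) essentially no allele still
segregates at the final generation (the sweep completes in ~400
generations), so full trajectories are the only data from which this
experiment is possible.

## Archaic introgression

Observations are per-1 kb-window counts of derived alleles on one
haplotype that are absent from the outgroup panel.  A two-state
(Human/Archaic) Poisson HMM is fit per haplotype by Baum–Welch
(convergence Δlog-likelihood < 10⁻⁴, max 500 iterations; emission rates
floored at 10⁻⁶; states relabelled each iteration so state 1 is the
high-rate state).  All haplotypes are fit in one batched pass (the
recursion is numba-compiled; a numpy reference implementation and an
exhaustive path-enumeration oracle back it in the tests); rows whose
fitted rates differ by less than 1.5× are degenerate — the expected
outcome on tract-free haplotypes — and contribute no segments.  Segments
are maximal runs of posterior P(Archaic) > 0.5, kept at mean posterior
≥ 0.8, then required to lie fully inside a candidate region and to share
≥ 1 aSNP (derived variant absent from the outgroup, inside the segment)
with any of the four archaic genotype panels.  Ancestry: more aSNPs
shared with the Denisovan than with the *union* of the three Neanderthal
panels → Denisova; the reverse → Neanderthal; ties → ambiguous.  Missing
archaic genotypes count as absence.

Region-level haplotypes are connected components of the aSNP graph with
edges at r² > 0.5 (computed on target-population chromosomes); each
segment joins the component sharing most of its aSNPs (ties to the
larger component); frequency = carrier chromosomes / population
chromosomes (2 × individuals — tracts are phased); the reported
haplotype is the most frequent one, its ancestry the majority over
member segments (ties → ambiguous), plus the max r² between the region's
candidate SNP and any cluster aSNP (high-LD flag at r² > 0.5).

## Association and enrichment

Phenotype correction is a two-step procedure: OLS residuals on
intercept + age + sex (heart rate, haemoglobin, blood pressure, BMI) or
+ height as well (chest depth, waist, weight, FEV1, PEF, FVC); residuals
are computed once and reused across SNPs.  The mixed model
`y = μ + gβ + u + ε`, `u ~ N(0, σ_g²K)`, `K = WWᵀ/m` from mean-centred
dosages, is fit by maximum likelihood after one eigendecomposition of K,
with a bounded scalar search over log₁₀(σ_g²/σ_e²) ∈ [−6, 6] and an
explicit check of the σ_g² → 0 boundary; the Wald test uses the unbiased
residual scale and a t reference with n−2 degrees of freedom, so with
K = I the test collapses exactly onto the OLS t-test.  Monomorphic SNPs
are flagged, not tested.  BH adjustment runs across SNPs within each
phenotype; adjusted p < 0.05 is suggestive, < 0.01 (0.05 over 5
correlated trait groups) strict.

Biobank-style lookup: exact position, else the nearest table SNP within
±50 bp (ties → smaller distance, then lower position), else a null match.
A phenotype counts as significant when log₁₀(p) < log₁₀(5·10⁻⁸/n_phen)
(−10.47 at n_phen = 1470).  The blood-count enrichment test resamples x
100-bp windows *without replacement* (the hypergeometric framing; the
Monte-Carlo p provably converges to the hypergeometric tail, which the
tests verify) from the universe of windows with ≥ 1 significant
association, counting windows with ≥ 1 significant blood-category
association; p uses ≥ ("at least as extreme"), with a strictly-greater
variant behind a flag.  Reported betas are never interpreted
directionally.

## Synthetic data

The generator emulates the statistical structure the scans rely on, not
a demographic history:

* **Frequencies.**  Ancestral frequencies are log-uniform on
  [0.02, 0.98] (density ∝ 1/p, the neutral-SFS shape); population
  frequencies are Balding–Nichols(F) draws around them (defaults
  F = 0.02 for the two focal populations, 0.15 for the outgroup —
  within-region vs continental-scale differentiation).
* **LD.**  Haplotypes are mosaics of K = 100 population founder
  haplotypes with Poisson switch points at ρ = 10⁻⁵/bp, so pair identity
  decays at ~2ρ per bp (tens of kb), at O(n·S) cost.  Defaults
  L = 1.5 Mb, S = 5,000 (~1 SNP / 300 bp), 54 + 74 + 54 diploids.  The
  founder pool adds ~1/K of apparent FST; the zero-drift limit test uses
  a large K to isolate the Balding–Nichols layer.
* **Sweeps.**  One designated sweep haplotype is copied onto carriers
  over per-carrier exponential extents (mean 100 kb per side), raising
  the focal derived allele to f* (default 0.9) in the target only.  This
  produces exactly the two signals the scans detect — frequency
  differentiation and shared long flanks — while keeping non-carrier
  backgrounds and all other populations untouched.
* **Archaic tracts.**  Each source lineage (one Neanderthal-like, one
  Denisovan-like) carries private derived alleles at density d = 10⁻³/bp
  at new positions (absent from the outgroup by construction — the aSNP
  premise) plus its own draw at shared sites; a fraction α (default 0.4,
  the regime the detector is validated in) of target haplotypes receives
  one tract covering a per-source anchor with exponential extents (mean
  tract 40 kb).  Anchoring makes the carriers of a source share a locus,
  as a real introgressed haplotype segregating at frequency α would.
  Divergence is modelled *only* as private derived alleles — no shared
  archaic polymorphism, no incomplete lineage sorting — which is
  sufficient for the aSNP logic but means ancestry assignment is easier
  than on real data.  The three Neanderthal pseudo-individuals each
  carry 90% of the Neanderthal-lineage private alleles; the Denisovan
  carries all of its own.
* **Phenotypes.**  `y = Σβ_j g_j + 0.05·age + 1.0·sex (+ 0.05·height) +
  N(0,1)`, age ~ U(18,65), sex ~ Bernoulli(0.5), height ~ N(160,7²)+12·sex.
* **Association tables.**  Uniform background p-values with plantable
  blood-category hits at chosen positions.

What passing tests therefore do **not** show: robustness to genotyping
error, phasing switch errors, recombination-rate variation, background
selection, realistic demography, or archaic shared polymorphism.  The
module's purpose is verifiable truth recovery, not realism.

## Problem sizes and numerical choices

The acceptance suite runs 20 seeds of the full scan and 20 of the
introgression pipeline at the study regime (5,000 SNPs, 128 focal
diploids), 200 null mixed-model simulations, 10⁵-draw calibrations and
50 trajectory fits; `scripts/acceptance.py` uses 10/8 seeds for the same
measurements.  These sizes put Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full run in minutes on one CPU.
Other numerics: transition-matrix rows are exact CDF differences (rows
sum to 1 within 10⁻¹⁰); likelihoods are floored at 10⁻³⁰⁰ before logs;
the EHH integrator treats a missing flanking direction (core at the data
edge) as contributing zero iHH, and sites where either population's iHH
is 0 are flagged missing and excluded from normalization.
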