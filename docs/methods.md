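# Methods

## Stutter error model

Reads at an STR are assumed to report the true allele's repeat copy
number except for stutter artifacts introduced during PCR or
sequencing, which add or remove whole repeat units. The model has three
parameters per locus (or per repeat-unit length): `u`, the per-read
expansion probability; `d`, the contraction probability; and `rho`,
governing a Geometric(ρ) step-size distribution on {1, 2, …} units.
Requirements: `u + d < 1`, `0 < rho ≤ 1`. The PMF is normalised over
all integers (each geometric tail sums to `u` and `d` exactly), which
the tests verify to 1e−9 by summation over ±200 units.

Two named presets set simulation conditions: `pcr_free`
(u = d = 0.005, ρ = 0.9; ~1% of reads carry stutter) and `pcr_plus`
(u = d = 0.05, ρ = 0.8; ~10%). These were chosen to match typical
stutter-read fractions of PCR-free and PCR+ short-read libraries; they
are defaults for simulation scenarios and CLI flags, not fitted
constants.

Fitting from data uses confidently homozygous calls (defaults
Q > 0.9, DP > 10): every non-matching read is counted as an error,
`u` and `d` are insertion/deletion read fractions over *all* reads,
and `rho` is the fraction of error reads with a one-unit step after
discarding error reads with steps > 10 units (unlikely to be stutter;
the exclusion deliberately applies to the ρ estimate only). With zero
error reads ρ is undefined; we assign 0.9 and flag the result
(`rho_floored`), matching the low-error regime such data implies.

Impure repeats can produce fractional copy numbers. The model is
defined on unit steps, so fractional differences are rounded to the
nearest integer step of at least 1 for the geometric exponent; exact
equality with the allele is required for the match branch. The sampler
redraws the (physically impossible, negligibly likely) event of a
negative copy number.

## Mosaicism inference

Given germline genotype ⟨A, B⟩, read vector R (length n), and stutter
model Θ, a mosaic allele C at fraction f on B's haplotype implies per-
read mixture weights ½, ½ − f, f on A, B, C. The likelihood is
maximised over both haplotype cases (short reads cannot phase the
mosaic), with ties broken toward B for determinism.

The estimator follows an alternating scheme: initialise f = 0.01; scan
integer-spaced candidate C across [min R − 3, max R + 3] (the lattice
is anchored on the observed read values, so fractional observed values
are themselves candidates; C = A and C = B are excluded since they
make f unidentifiable); maximise f ∈ [0, 0.5] at the chosen C by
bounded scalar optimisation (`scipy.optimize.minimize_scalar`,
xatol = 1e−6, endpoints checked explicitly); repeat until the
log-likelihood improves by < 1e−6 or 100 iterations. A final polish
sweep optimises f for every candidate C and keeps the argmax, so the
coordinate scheme cannot terminate in a joint local optimum; the
acceptance suite checks the result against an exhaustive (C × f) grid
to 1e−4 on 50 random instances. Ties in the C scan resolve to the
candidate closest to a germline allele, then the smaller C. Per-read
mixture probabilities are floored at 1e−300 before logs so a
misspecified Θ cannot yield −inf. Reads are collapsed to unique values
with counts before any likelihood work; all evaluations are vectorised
over that compressed support.

The test of H₀: f = 0 uses λ_LR = −2[log L(Ĉ, 0) − log L(Ĉ, f̂)] with
the *same* Ĉ in both terms (at f = 0 the likelihood does not depend on
C, so no separate null optimisation exists). Because f = 0 lies on the
boundary, the null reference distribution is a 50:50 mixture of a
point mass at 0 and χ²(2): p = 1 when λ = 0, else p = ½·Pr(χ²₂ ≥ λ).
Tiny negative λ from numerics (> −1e−8) are clamped to 0.

Calibration is approximate, and the simulations quantify how: at
PCR-free error rates and 50× coverage, the probability that a
replicate contains *no* stutter-error read is 0.99⁵⁰ ≈ 0.60, and all
such replicates give λ = 0 exactly, so the point mass exceeds ½ and
tail probabilities below nominal α ≈ 0.1 are conservative, while
empirical type-I error at α = 0.05 and 0.01 sits within binomial noise
of nominal. At higher coverage the max-over-C selection makes the test
mildly anti-conservative instead. The acceptance suite asserts the
nominal calibration claim at α ∈ {0.01, 0.05, 0.1}; the α = 0.1 case
documents the conservative regime.

A related discreteness effect shapes power at very small f: with a
homozygous background and f ≈ 0.01, most detections rest on a single
mosaic read, whose likelihood-ratio contribution *shrinks* as coverage
grows (the optimal f scales like 1/n), so power at a fixed α = 0.05
threshold is not monotone in coverage there (≈ 0.45 at 50× vs ≈ 0.32
at 100×, stable across seeds). Everywhere else on the studied grid
power rises with f, with coverage, with the mosaic allele's distance
from the germline alleles, and is at least as high for heterozygous as
for homozygous backgrounds.

## Call exclusion and filtering

Calls are excluded before testing when they have no read support, a
missing genotype, no read support for either called germline allele,
or reads at only one distinct length (mosaicism untestable). Candidate
mosaic calls are then screened with Benjamini–Hochberg adjustment
(step-up, computed directly; tests cross-check statsmodels to 1e−12)
and hard thresholds, all boundaries inclusive as stated: mosaic
support ≥ 3 reads exactly matching Ĉ, depth ≥ 10, f̂ ≤ 0.3 (larger f̂
indicates a mis-genotyped heterozygote rather than mosaicism), quality
≥ 0.8, adjusted p < 0.05. FDR adjustment defaults to per-sample
(testing is per-sample) with a cohort-wide option. Loci called mosaic
in > 10 samples of a cohort are flagged recurrent; loci intersecting
user-supplied BED regions (e.g. hard-to-map tracks) are flagged
`excluded_region`, with the VCF 1-based position converted to 0-based
half-open for the overlap.

`mosaic_support` counts reads whose copy number equals Ĉ exactly after
the I/O conversions — the simplest reproducible definition.

## Simulators

**Read-count vectors.** Each read draws its source allele from
{A: ½, B: ½ − Σfᵢ, Cᵢ: fᵢ} (k ≥ 0 mosaic alleles; Σfᵢ ≤ ½) and then
passes through the stutter model. Sampling is inverse-CDF with exactly
three uniforms per read, so for a common seed, low-coverage vectors
are prefixes of high-coverage ones and raising f converts B-reads to
C-reads read-by-read — a variance-reduction device for grid
comparisons; the distribution is identical to sequential sampling
(chi-square goodness-of-fit in the tests). Power experiments run 200
replicates per setting by default (2000 for null calibration) and
supply the true ⟨A, B⟩ to the estimator: this strategy evaluates the
likelihood machinery in isolation, assuming genotyping is correct.
Per-replicate RNG streams spawn deterministically from one master
seed.

**Raw reads.** For pipeline-level testing, the read simulator builds
one haplotype sequence per (allele, stutter variant) — variants kept
while their stutter probability exceeds 1e−4 — by resizing the
reference repeat tract, then draws single- or paired-end reads with
uniform start positions within a window around the tract, proportional
allocation across variants, uniform base-substitution errors, constant
Q30 qualities, and strand flipped with probability ½. This is a native
generator: uniform starts and a uniform error profile are deliberate
simplifications relative to platform-specific read simulators, and
GC/coverage bias, quality-dependent errors, alignment artifacts and
duplicate reads are not modelled. Synthetic VCF fixtures built from
the read-count simulator likewise emulate only the fields this tool
consumes (GT, Q, DP, MALLREADS with integer bp offsets); passing tests
therefore validate the statistics under the stated error model, not
robustness to upstream genotyping or alignment failure modes on real
data.

## Numerical and design choices

- Problem sizes: 2000 replicates for null calibration, 200 per power
  or recovery cell, 100-locus end-to-end fixtures — large enough that
  binomial noise is well below the asserted tolerances.
- Degenerate input (all reads equal to a homozygous genotype) yields
  f̂ = 0, p = 1 by construction; the call-exclusion rules drop such
  loci before testing in the VCF path.
- Convergence tolerance 1e−6 on the log-likelihood and max 100
  iterations are not critical: the f-likelihood at fixed C is smooth
  and the C grid finite, so convergence typically takes 2–3 cycles.
- Multi-sample VCFs are processed sample-by-sample; the model is
  strictly per-sample.
- Coordinates stay in VCF 1-based convention internally; only the BED
  overlap converts.

## Known limitations

- The likelihood models a single mosaic allele; with several true
  mosaic alleles the returned f̂ lands between the largest single
  fraction and their sum, and power is comparable to the single-allele
  case at the same total fraction.
- The 50:50 point-mass/χ²(2) null is an approximation (two parameters
  are estimated, C by discrete search); see the calibration discussion
  above.
- Stutter parameters are taken as known per locus or per period;
  locus-specific EM estimation from heterozygous data is out of scope.
- The raw-read simulator does not emulate platform error profiles and
  there is no built-in aligner/genotyper; end-to-end claims stop at
  the VCF interface.
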