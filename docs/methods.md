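# Methods

## Model

A biallelic locus in a panmictic diploid population of effective size Ne
evolves under the discrete Wright–Fisher model with selection. With focal
allele `A` at frequency `p` and genotype fitnesses `1+s2 : 1+s1 : 1`
(`AA : Aa : aa`), the next generation's frequency is
`Binomial(2Ne, p') / 2Ne` with

    p' = p + p(1-p) · (s1(1-2p) + s2 p),

approximated for inference by a normal with mean `p'` and variance
`p(1-p)/(2Ne)` (the diffusion limit). `s1, s2 > -1` is the meaningful
fitness domain; the estimation machinery operates on all of R².

The data are temporal samples: at 1-based generations `t_1 < … < t_K ≤ T`,
`a_t` focal alleles among `n_t` sampled haplotypes (`n_t = 0` where
unsampled). The population frequency is latent. We discretize it onto
`M` Chebychev nodes `g_i = (1 + cos(πi/(M−1)))/2`, sorted ascending, and run
an HMM with:

- transition `P(i→j)`: the normal kernel centered at `μ_i = p'(g_i)`
  integrated over the interval `[(g_{j−1}+g_j)/2, (g_j+g_{j+1})/2]`, with
  the two outer interval edges at ∓∞ so that mass leaving [0,1] is absorbed
  into the boundary states; the fixed states `g = 0, 1` are exact point
  masses (zero drift variance, matching the diffusion's absorbing
  boundaries);
- emission `a_t ~ Binomial(n_t, g_i)`; fixed states emit deterministically;
- initial distribution: a beta law `(α, β)` discretized by its integral over
  each node's interval (tail mass accrues to the boundary states); either
  held fixed (`α = β = 1`, the uniform density) or estimated.

Chebychev spacing matters: with equidistant nodes the kernel near the
boundaries becomes narrower than the node spacing and the discretized
transition degrades — equidistant grids are supported only as a test
fixture.

## Estimation

The fit alternates:

1. **E-step** — scaled forward–backward over all T generations, giving the
   data log-likelihood and the posterior-expectation sums over transitions
   `Σ_t E[H_t]`, `Σ_t E[F_t H_t]`, `Σ_t E[F_t² H_t]`, `Σ_t E[F_t F_{t+1}]`,
   `E[F_1]`, `E[F_T]` with `H = F(1−F)` (sums over `t = 1…T−1`).
2. **M-step** — the expected Gaussian path log-likelihood is an exact
   quadratic in `(s1, s2)`; its stationary point is solved in closed form
   (a 2×2 linear system). One-parameter modes restrict to the line
   `a·s1 = b·s2`; the restricted maximizer is the 1-D closed form
   `(v·L)/(v·Av)` along the direction `v` spanning the line — algebraically
   what the Lagrange-multiplier treatment yields, with λ eliminated.
3. **Initial-distribution step** — `(α, β)` maximize
   `Σ_m γ(1, m) · ln p(m; α, β)` numerically (Nelder–Mead on log-shapes,
   bounded in [1e-3, 1e3]). Inside the EM loop this update is warm-started
   and capped (a generalized-EM partial step); called standalone it runs to
   convergence.

Because expectations come from the discretized model while the M-step
maximizes the continuous path likelihood, the iteration is a *hybrid* EM:
monotone ascent is not guaranteed. The loop therefore (a) always performs at
least `min_iters = 5` iterations, (b) stops when the log-likelihood changes
by less than `tol = 1e-3`, and (c) reports the maximum log-likelihood over
the trace together with the parameters that achieved it. Without (a), fits
on weak-signal data freeze at the `s = 0` starting point and pile p-values
at 1. Defaults: `M = 500`, `s1⁰ = s2⁰ = 0`, `α⁰ = β⁰ = 1`, max 500
iterations (non-convergence is flagged, not discarded).

`M = 500` balances accuracy and cost; estimates are stable for `M ≥ 250`
and biased downward below that. Bulk simulation studies in the test suite
use `M = 250` for the selection fits; the Ne estimator uses `M = 500`
because the composite-likelihood argmax is noticeably inflated by coarse
discretization (about +50% at `M = 250` vs +20–25% at `M = 500` in the
standard design).

### Numerical implementation

The transition matrix is effectively banded: the kernel's standard deviation
(≤ `sqrt(0.25/(2Ne))`) spans only a handful of grid intervals. Rows are
stored as ±12-standard-deviation windows with the (< 1e-30) tail mass folded
into the window edges, keeping rows exactly stochastic; a numba kernel runs
the forward–backward pass over this representation. A dense numpy
forward–backward is retained as the reference path (used automatically when
a dense matrix or the joint posteriors `ξ` are requested) and the two are
asserted equal to 1e-10 in the tests. Scale factors are accumulated only at
sampled generations (elsewhere the forward vector stays normalized because
rows sum to one exactly). Zero-likelihood data report `-inf` rather than
raising.

## Tests against neutrality and mode classification

For one alternative mode, `D = 2(ll_s − ll_0)` with `(α, β)` re-estimated
under both hypotheses (nuisance parameters); `p = P(χ²(1) > D)`. Small
negative `D` from numeric noise is clamped to zero. With multiple
alternatives, `δ = −2(ll_0 − max(ll_add, ll_dom, ll_rec, ll_het))`, also
referred to χ²(1) — deliberately simple and mildly anti-conservative near
the 5% level (rejection rate ≈ 6% under neutrality in the standard design);
χ²(2) calibrates worse and is available only for comparison. Significant
loci are labelled by the argmax mode, ties broken in the fixed order
additive → dominant → recessive → het-diff (and flagged); het-diff splits
into overdominant/underdominant by the sign of ŝ1.

## Effective population size

Ne has no closed-form EM update, so it is estimated on a grid: each locus
contributes its neutral HMM log-likelihood (uniform initial density, never
co-estimated) conditioned on the samples being polymorphic overall —
dividing by `1 − P(no focal alleles) − P(no non-focal alleles)`, both terms
computed as HMM likelihoods of all-zero / all-fixed pseudo-data. The
composite surface over a default grid of 9 log-spaced values spanning
`[guess/8, 8·guess]` is interpolated by a cubic spline in `(log Ne, ll)` and
maximized on a dense grid. Loci failing the polymorphism precondition are
skipped and counted. Loci sharing a sampling scheme are processed in one
batched forward pass using matrix powers between sampling times. Estimates
are slightly biased upward (see above re: discretization) with low variance.

## Simulator

Forward binomial Wright–Fisher with absorbing boundaries; time-varying Ne
enters the reproduction variance per generation (and the 1-over-i initial
law through the first generation's Ne). Initial conditions: fixed `p`, the
neutral standing-variation law `P(i) ∝ 1/i` on `i ∈ {1,…,2Ne−1}`, or
explicit per-replicate frequencies (the hook for data-matched designs).
Sampling thins the planned `n_t` by a missingness probability, then draws
`Binomial(n_eff, p_t)`. Segregation conditioning is applied to the
*samples* by rejection: directional modes require `A` not fixed in the first
sampled timepoint and not lost in the last; overdominance requires `A`
segregating in the last; underdominance in the first; neutral replicates use
the directional rule. One root seed spawns per-replicate streams; outputs
are byte-reproducible.

What the simulator deliberately does not emulate: linkage between loci
(replicates are independent), ascertainment of SNP panels beyond the
explicit-initial-frequency hook, sequencing error, and population structure.
Passing calibration tests on these simulations therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to structure, migration, or ascertainment in real data.

## Genome scan

Per-SNP filters (defaults from the ancient-DNA use case): data at ≥ 2
timepoints, strictly more than 50 samples in total, pooled minor-allele
frequency strictly above 0.05. Post-processing combines each SNP's p-value
with its 50-SNP window (25 upstream, 24 downstream, focal included;
truncated at chromosome ends and rescaled by `50/actual`): the sum
`S = −Σ log p` is referred to a scaled χ² fitted genome-wide by moment
matching (`c = Var/2Mean`, `f = 2Mean²/Var` — Brown's estimator). Regions
are contiguous runs of post-processed BH significance containing at least
one SNP significant under both the raw and post-processed BH thresholds;
the lead SNP is the member with minimal raw p. Confidence intervals for a
lead SNP's ŝ come from a parametric bootstrap at the fitted mode,
coefficient, initial frequency, scheme and Ne, with additive mean-bias
correction before taking the 2.5%/97.5% quantiles (the bias-correction form
is a documented choice). The moment-matched null is fitted to *all* window
sums, so it assumes signal regions are a small fraction of the genome; in
toy data the signal fraction must be kept genome-like (a few percent) for
the post-processing to behave as intended.

## Validation studies and desk-scale sizes

The test suite runs the validation studies at reduced scale; sizes are
package choices recorded here:

- *Calibration under neutrality*: 600 replicates of the standard design
  (Ne = 10⁴, T = 251, p0 = 0.25, 11 × 50 haploids), all modes fitted at
  M = 500 (the single-alternative p-value calibration is measurably cleaner
  at 500 states than at 250). The δ rejection rate at 0.05 is checked
  against [0.04, 0.09]; per-mode single-alternative p-values are checked for
  uniformity with the KS statistic at its 95% sampling quantile `1.358/√n`
  for the scale used. `scripts/acceptance.py` recomputes the δ rejection
  rate independently at 1,500 replicates with M = 250.
- *Parameter recovery*: 60 replicates per (mode, s) at s ∈ {0.025, 0.05};
  the median ŝ must fall within 20% of truth (median Monte-Carlo error ≈ 3%
  of s at this scale).
- *Worked example*: the bundled ASIP series, full and truncated, M = 500.
- *Ne recovery*: 6 batches × 1,000 neutral loci at true Ne = 10⁴, grid
  guess 5,000; estimates within a factor 1.5 of truth, median bias ≥ 0.
- *Oracle equivalences*: forward–backward vs exhaustive path enumeration
  (M = 3, T = 3, 1e-12); closed-form M-steps vs polished numeric optimizers
  on 100 random accumulator sets (1e-8); trajectory MLE vs numeric path
  likelihood maximization (1e-6); transition rows vs adaptive quadrature
  (1e-8).

## Known limitations

- Constant Ne during inference; time-varying histories are handled by the
  constant-Ne heuristic (estimate a single Ne from neutral loci, then fix
  it), which is adequate for smoothly varying histories but untested for
  bottlenecks or exponential growth.
- The χ²(1) reference for δ is anti-conservative near the threshold; for
  decision-critical applications, calibrate by parametric bootstrap in the
  scenario of interest (the simulator makes this cheap).
- The discrete transition operator carries sub-grid noise within one node
  spacing of the boundaries (e.g., row-wise expected change under weak
  positive selection can dip below zero there); all likelihood computations
  integrate over this scale and are unaffected.
- Unconstrained 2-D fits have higher variance than the one-parameter modes,
  especially for underdominance; explore the bespoke modes first.
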