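# Methods

## The Lehmer transform and its numerical evaluation

For a strictly positive sample x₁,…,xₙ the transform
L(s) = Σxᵢˢ / Σxᵢˢ⁻¹ is a ratio of consecutive power sums; it is the
Lehmer mean of order s and sweeps monotonically from min x (s → −∞) to
max x (s → +∞) whenever the sample has two distinct values.  Power sums
are evaluated in log space (log-sum-exp with the dominant term factored
out), which keeps the evaluation exact to machine precision for |s| up
to several hundred even on samples spanning six decades.  Beyond
|s| = 700 (configurable constant `LARGE_S_CUTOFF`) the transform is
numerically indistinguishable from the extreme order statistic and is
returned as exactly max/min.

The first derivative uses the closed form
L(s)·[Σxᵢˢ log xᵢ/Σxᵢˢ − Σxᵢˢ⁻¹ log xᵢ/Σxᵢˢ⁻¹], i.e. the difference of
log-value means under two softmax weightings — manifestly nonnegative,
zero only for constant samples.  An equivalent pairwise double sum
Σ_{i<k}(xᵢ−x_k) log(xᵢ/x_k)(xᵢx_k)ˢ⁻¹ equals this derivative only after
division by (Σxᵢˢ⁻¹)²; the test suite asserts both routes agree to
1e−10, pinning the normalization down.  Higher-order derivatives are
served by nested central differences of the analytic first derivative;
only order one is used anywhere in the pipeline.

Raw EEG traces cross zero, so every pipeline starts with an invertible
affine map onto a positive target range (default [1, 2]); the map's
parameters are returned so the original mV scale can be restored.  The
map preserves relative sample positions, so any two affine decorations
of the same trace positivize to the identical signal.

### Inversion

The production inverse is monotone root finding: an expanding bracket
around s = 0 followed by Brent's method, with the boundary statistics
max x / min x mapped to ±∞ and a constant signal rejected explicitly
(the transform is not injective there).  Round-trip error is below
1e−8 across s ∈ [−10, 10].

The power-series inverse (Lagrange–Bürmann inversion of t = L(s) about
an expansion point s₀) is kept as a diagnostic: Taylor coefficients of L
at s₀ are estimated by a least-squares polynomial fit on Chebyshev nodes
in a ±0.5 window, the series is reverted by fixed-point composition, and
the K-term truncation (default K = 8) is returned.  No convergence
radius is claimed; when the term magnitudes stop decreasing a
`SeriesDivergenceWarning` carrying the partial sum is emitted.  Empirically
the series tracks the root-finder to ~1e−4 within roughly |s − s₀| ≲ 0.2
on small test signals and diverges for distant targets.

### Pointwise suddency moments

`pointwise_inverse_series` maps every sample to its own suddency moment
s_i = L⁻¹(x_i).  It is vectorized (monotone grid seed + Newton polish)
and agrees with the per-sample root-finder to ~1e−10 in the interior.
Extremal samples, whose exact inverse is ±∞, are clipped to ±clip
(default 20, configurable; treated as a convention, not ground truth).
A consequence worth knowing: for *dense* smooth signals the suddency
law genuinely has heavy tails — many samples near the empirical extremes
need |s| far beyond the clip, so mass piles up at ±clip.  Windowing
defaults (window 256 samples = 1 s at 256 Hz, hop 128) are likewise
conventions.

## The action potential distribution

With the signal affinely rescaled to the boundary conditions
L(−∞) = exp{W₀(0)} = 1 and L(+∞) = exp{W₀(αβ)/(αβ)} ∈ (1, e), the
distribution function F(s) = A + B·L(s)^{1/α} e^{βL(s)} runs from 0 to 1
when B = 1/(D − e^β), D = exp{W₀(αβ)/(α²β) + β e^{W₀(αβ)/(αβ)}}, and
**A = −B e^β**.  The sign of A is forced by the limits: a positive A of
the same magnitude gives F(−∞) = 2e^β/(D − e^β) ≠ 0, and a regression
test keeps that fact on record.  The density follows by differentiation;
its normalization constant C equals B.  All Lambert-W evaluations use
the package's own Halley iteration (residual < 1e−12), cross-checked
against `scipy.special.lambertw` in the tests.

Sampling is inverse-CDF (monotone grid + Newton polish on the closed
form), exact to ~1e−10 and reproducible under a fixed seed.  Quadrature
uses an adaptive scheme on s ∈ [−50, 50]; the fixtures used for
normalization checks are deliberately two-level signals ([1, 2]-like),
because the bracket captures all but <1e−8 of the mass only when
adjacent rescaled values have ratios ≳ 1.5 — for dense signals the
suddency tails extend far beyond any fixed bracket, and the five
channel statistics are then integrals over the bracket by construction.

The membrane voltage functional V(t; c) (Lambert-W branch on (0, 1/e),
t²eᵗ − 1/e and t²e⁻ᵗ − 1/e beyond) is implemented on the open intervals
as printed; the breakpoints are left undefined and raise, rather than
inventing a gluing the formulation does not specify.

### Maximum likelihood

What constitutes an "observation" of S is an interpretation: the package
fits the pointwise suddency moments of the (positivized) channel, i.e.
the `signal_to_smoments` output, which is the construction that the
anomaly-screening view of a signal suggests.  The likelihood is
maximized over unconstrained coordinates (logit α, log β) with
Nelder-Mead and seeded multistart (default 3 starts; the featurizer uses
2 — the per-channel surfaces proved smooth and unimodal in pilots).
Because the boundary conditions depend on (α, β), the signal is
re-rescaled at every candidate; this keeps the density valid at each
step at the cost of one affine map per evaluation.  On simulated draws
(n = 5000 from (α, β) = (0.6, 2.0) on a two-level fixture) the fit
recovers α within ±0.05 and β within ±0.2 on every one of 20 seeds,
with no detectable bias (mean errors ≈ −0.002).

## Features

Per channel: positivize → pointwise suddency moments (clip 20) → MLE →
constrained modes m₁ = argmax_{s≤1} f, m₂ = argmax_{s≥1} f (coarse 0.01
grid, ties toward 1, golden-section refinement; search half-width 50) →
three adaptive-quadrature integrals of f·log f over
[−50, m₁], [m₁, m₂], [m₂, 50] and the tails F(m₁), 1 − F(m₂).  The
integrals are stored with the printed (non-negated) sign; differential
entropy is −∫f log f, and the heatmaps use that standard sign.  Both
conventions are exposed to avoid silent flips.

Assembly is experiment-major (EC, EO, TASK), then channel in 10–20
label order, then the five statistics — 5·M·J entries per subject.
Missing channels or whole experiments are masked and imputed with the
per-feature median over the subjects that have the entry; inside cross
validation the medians come from the training fold only.  Constant
channels yield a missing result rather than an error; subjects with no
usable experiment are excluded with a warning.  Heatmaps aggregate
per-group means (mean vs median was an open choice; mean is the
package's).

## Classification

BADT is plain bagging over full-depth decision trees (200 trees, no
feature subsampling), GNB the standard per-class univariate-normal
model with a 1e−9 variance floor; both via scikit-learn behind the
module surface.  Evaluation repeats stratified k-fold CV (default
10-fold × 100 replications; reshuffled each replication, seeded),
aggregates fold confusion matrices, and reports accuracy, sensitivity
and specificity (MDD positive) as means ± standard errors over
replications.  The latent "Mixed" label is a margin-based heuristic
(out-of-bag class-probability margin < 0.1 relabels an instance for a
second pass; predictions of "Mixed" resolve to the majority binary
vote) — it is an interpretation of a sub-type idea, off by default.

## Synthetic data: what it emulates and what it does not

The generator plants exactly the statistical structure the analysis
assumes.  Because F depends on s only through L(s), the law of the
*values* V = L(S) has the closed form G(v) = A + B v^{1/α} e^{βv} on
(1, Lmax) — independent of the signal's shape.  A channel is therefore
drawn i.i.d. from G (inverse-CDF with Newton polish), so the pointwise
suddency moments of the draw, taken with respect to the draw itself,
follow the APD with the generating parameters; interior moments equal
the per-sample root-finder inverse to ~1e−13 (the exact round-trip),
and the distributional agreement is exact up to clipping and an O(1/n)
empirical-extremes effect.  Gaussian observation noise (default 1% of
the signal range) is added after construction and breaks the exact
round-trip by a bounded amount; an affine decoration to an mV-like
scale follows, which downstream positivization undoes exactly.

Defaults mirror a clinical EEG protocol: 19 channels × 3 experiments at
256 Hz for 10 s, ~32 subjects per class; a realistic missing-data preset
(5.5% control / 6.9% MDD subject-experiments, by experiment) is
available via `MISSING_RATES_HUSM` + `inject_missing`.  Class parameters
default to H: (α 0.8, β 1.0) vs MDD: (α 0.45, β 2.5) with the 1% noise —
calibrated once so the two classes are clearly separable by the
pipeline's own features, then frozen.  What the generator does *not*
emulate: 1/f spectra, oscillatory band structure, artifacts, spatial
correlation between electrodes, or any physiological realism — passing
tests demonstrate the pipeline's internal consistency and its power to
detect APD-parameter differences, not clinical performance on real EEG.

## Problem sizes in the test suite

The stage tests run at reduced sizes chosen as the package's own test
conditions: the full-layout assembly check uses 2+2 subjects with 0.5 s
recordings (the 285-column structure does not depend on duration), and
the classification check uses 32+32 subjects, 4 channels, one
experiment, 1 s recordings with 10-fold × 20-replication CV.  Generator
defaults remain at the study-scale layout.

## Known limitations

- The clip at |s| = 20 censors the genuinely heavy suddency tails of
  dense signals; the MLE therefore fits a censored sample with an
  uncensored density.  Fitted (α, β) are consistent featurizers, not
  unbiased estimates of generating parameters for dense signals.
- The Lagrange–Bürmann series has no characterized convergence region;
  it is a diagnostic only.
- Only the first derivative of the transform is analytic.
- The "Mixed" augmentation is a heuristic; nothing guarantees it helps.
- EDF input requires `mne` and is untested offline (no EDF writer
  available); delimited matrices are the tested path.
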