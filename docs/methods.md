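# Methods

## The estimator

`densitycloud` visualizes how two groups, a reference B and a comparison
A, differ across an entire d-dimensional distribution (2 ≤ d ≲ 10). The
object of interest is the local density ratio f_A(x)/f_B(x), estimated at
a large set of probe points with a k-nearest-neighbor estimator:

    f̂(x) = (1 / (N·V_d)) · Σ_{j=1..k} j^(2/d) / [Σ_{j=1..k} ||x_j(x) − x||²]^(d/2)

where V_d = π^(d/2)/Γ(d/2+1) is the unit-ball volume and x_j(x) the j-th
nearest sample point in Euclidean distance. k-NN estimates sidestep the
cost blow-up of multivariate kernel density estimation. The estimator is
mildly biased upward in larger samples, so before estimation the smaller
group keeps all of its rows and is topped up to the larger group's size
by seeded resampling with replacement. With equal group sizes the ratio
collapses to

    f̂_A(x)/f̂_B(x) = [Σ_j ||x_jB − x||² / Σ_j ||x_jA − x||²]^(d/2),

which is what `relative_density` evaluates; it is algebraically identical
to the quotient of two full estimates (asserted to 1e−12 in tests).
Distances are unscaled Euclidean on the variables as given: the intended
inputs are commensurate scores; standardize beforehand otherwise.

## Probes

Probes are drawn with replacement from the pooled data (both groups,
original sizes) and jittered with independent per-variable normal noise,
SD = 0.2 × the pooled variable SD by default. Jitter fills sparse regions
and smooths the clouds, at the price of blurring sharp features (floors,
ceilings, quantized scores). The probe count follows the schedule
round(6000 + 10000/d), clamped to [7000, 11000] — 11,000 at d=2 shrinking
to 7,000 at d=10 — because panels get smaller as the scatterplot matrix
grows. A single probe set is generated per analysis from the original
(pre-equalization, pre-transformation) data and shared by every component
of a decomposition sequence; this makes the component ratios exactly
multiplicative and the plots directly comparable.

## Choice of k

Default k = round(√N) on the equalized group size; a 1%-of-N rule and an
explicit k are available. Rounding is half-away-from-zero throughout.
Larger k smooths noisy estimates but makes neighborhoods less local: for
uniform data the edge of the smallest hypercube holding the k nearest
neighbors is (k/N)^(1/d), which at k = N/100 already spans ~52% of the
space at d=7 and ~63% at d=10 — the reason the tool targets d ≲ 10.

## Decomposition sequences

The overall ratio A/B is factored by comparing adjacent stages of a
transform chain built from the equalized reference sample:

| stage | transform | matches A's |
|---|---|---|
| B_shift | translate | centroid |
| B_shift_scaled | + per-variable rescale about the mean | centroid, SDs |
| B_shift_scaled_colored | + ZCA-cor whiten/recolor | centroid, SDs, correlations |

Components: location = B_shift/B, scale = B_shift_scaled/B_shift,
covariation = B_shift_scaled_colored/B_shift_scaled, and a (residual)
shape term with A in the numerator. Sequences LS, LSS and LSCS multiply
elementwise to the overall ratio exactly, because all densities come from
the same probe set and the same equalized samples; LSS+ (5 plots) and
LSCS+ (7 plots) add the intermediate components. Target moments for the
transforms are taken from the equalized A sample — the same rows whose
density is estimated.

ZCA-cor whitening, W = R^(−1/2) V^(−1/2) with coloring inverse
V^(1/2) R^(1/2) (R the correlation matrix, V the diagonal variance
matrix), is the whitening variant whose output stays maximally correlated
with the input variables, so the recolored data remain interpretable
variable-by-variable. Matrix square roots use a symmetric
eigendecomposition with an eigenvalue floor of 1e−10; a smallest
correlation eigenvalue below 1e−8 aborts with a near-singularity error.
Variances and SDs use the n−1 denominator everywhere.

## Random-split diagnostic

Even identical populations produce ratio fluctuations. The diagnostic
halves group A and group B separately at random, pools opposite halves
into two pseudo-groups (so group membership cannot drive the ratio),
equalizes their sizes, and recomputes the relative density with the same
probes and k. Overlaid smoothed curves of actual vs null log ratios show
whether the observed tails exceed estimation noise. One split is the
default; extra splits are pooled for a smoother null. The comparison is a
visual diagnostic, not a formal test: probe-level ratio values are
spatially correlated (nearby probes share neighbors), so classical
two-sample tests applied to per-probe values are anticonservative when
probes are dense. The calibration test in the suite therefore uses 250
probes for n = 2,000/group (~n/8), sparse enough that the iid
Kolmogorov–Smirnov critical value is approximately valid.

## Rendering

Each probe appears in every pairwise panel of a d×d scatterplot matrix
(variable names on the diagonal, both triangles drawn). Color encodes the
ratio's direction (blue where the comparison group is denser, pink where
the reference group is), and opacity its magnitude:
alpha = min(1, |log ratio| / reference_max). A ratio of one is invisible;
the most extreme ratio — taken globally across a sequence (default, so
component strengths are visually comparable) or locally per component —
is fully opaque. Log-scale normalization compresses outliers. Each figure
is annotated with the displayed ratio range; draw order is shuffled
(seeded) so neither color systematically overplots the other. Point size
defaults to 14/d. Exact colors and sizes are aesthetic choices.

## Synthetic scenarios

The generator draws group B from N(0, R_B) (unit variances) and group A
from N(μ, D·R_A·D), D = diag(sd_ratio), with the centroid shift specified
in units of the per-variable pooled population SD. An optional hard
ceiling clips values at per-variable upper limits — for the whole dataset
or one group — shrinking variance and inducing negative skew, the
signature of bounded questionnaire scores. Gaussian scenarios were chosen
because their closed-form densities give an exact log-ratio oracle for
the estimator; what they do not emulate is the skewness, kurtosis,
quantization and mixed marginals of real rating data, so passing tests
demonstrate correctness of the machinery, not robustness to arbitrary
real-world distributions.

## Problem sizes and numerical choices in the test suite

Stochastic checks run at n = 2,000–5,000 per group with 250–2,000 probes,
sizes at which each check's expected effect exceeds its Monte-Carlo noise
by a wide margin while the whole suite stays fast. Degenerate cases: a
probe coinciding with ≥ k sample points gets a machine-precision distance
floor (with a warning) instead of an infinite density; an all-ones ratio
field renders fully transparent with a warning; neighbor ties are
resolved by sample index, which cannot change the distance sums. Natural
logs are used for log ratios (rendering normalizes, so the base is
display-irrelevant).

## Limitations

- No formal inference: no confidence bands or permutation p-values; the
  random-split curve is a visual aid.
- k-NN estimates degrade with dimension (distance concentration); beyond
  d ≈ 10 the schedule clamps and a warning is emitted.
- Only two groups, complete cases only, Euclidean distances on the raw
  scales; higher-moment decomposition steps beyond covariation are out of
  scope.
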