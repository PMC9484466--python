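# Methods

## Model

Observations are modeled as independent draws from the delta-gamma
distribution Δ(δ, α, β): an observation is exactly 0 with probability
δ ∈ [0, 1) and otherwise follows a gamma distribution with shape α > 0 and
scale β > 0.  The zero count n₀ in a sample of size n is therefore
Binomial(n, δ), and the n₁ = n − n₀ positive values are iid gamma.  The
target of inference is the variance

    τ = (1 − δ)·αβ² + δ(1 − δ)·(αβ)².

The model assumes independence across observations and a *structural*
zero class: zeros are produced by a separate mechanism, not by rounding
small positive amounts.

Two parameterization conventions coexist in this literature, and the
package is explicit about both: distributions are represented internally
as shape + scale, while the closed-form estimator β̂ = α̂/x̄ is a **rate**
and is reported as such (`MleEstimates.rate_hat`, with `scale_hat = 1/rate_hat`).

## Point estimation

With δ̂ = n₀/n and the positive-part mean x̄₊, the package uses the
classical closed-form gamma approximations

    α̂ = 0.5 / (log x̄₊ − mean log x₊),    β̂ = α̂ / x̄₊  (rate),

and the plug-in τ̂ from the variance formula.  This α̂ is the standard
first-order approximation to the gamma likelihood equations, kept
deliberately instead of the Newton-iterated exact MLE because the interval
constructions below are defined in terms of it.  The exact likelihood is
used only where likelihoods themselves are compared: the AIC/BIC model
screening maximizes the exact gamma log-likelihood numerically (seeded at
the closed form), since information criteria are meaningless on an
approximate likelihood.  Samples in which all positives are equal make
the denominator of α̂ vanish and raise a typed error, as do samples with
fewer than two positives.

## The cube-root (Wilson–Hilferty) bridge

For Y ~ gamma(a, b), Y^⅓ is approximately normal with

    μ = (ba)^⅓ (1 − 1/(9a)),    σ² = b^⅔ / (9 a^⅓).

Inverting this pair gives closed forms for the shape, scale, mean M = ab
and variance V = ab² implied by any (μ, σ²) with σ² > 0:

    a = (1/9)·{t + √(t² − 1)},  t = 1 + μ²/(2σ²)
    b = 27 a^½ (σ²)^{3/2}
    M = {μ/2 + √((μ/2)² + σ²)}³
    V = 9σ²·{(μ + √(μ² + 4σ²))/2}⁴

The maps are exact inverses of the approximation (the test suite verifies
round-trips to 1e-8 over a wide parameter grid), are defined for negative
μ draws, and always return positive M and V.  Every interval method draws
(μ, σ², δ) triples by its own logic, pushes them through M and V, and
assembles τ draws as (1 − δ)V + δ(1 − δ)M².  All cube-root statistics
(x̄, s² with the n₁ − 1 denominator) are computed from the positive
observations only: cube roots of structural zeros carry no information
about the gamma component, and s² with n₁ − 1 degrees of freedom is what
the χ²_{n₁−1} pivot below distributes.

## Interval constructions

All intervals are cut from m Monte Carlo τ draws.  Equal-tail intervals
take the (α/2, 1 − α/2) empirical quantiles with linear interpolation
between order statistics ("type 7", the default of essentially every
numerical environment; the convention matters at the third decimal for
m = 5000).  HPD intervals use the empirical shortest-window rule: among
all windows of w = ⌈level·m⌉ consecutive sorted draws, the shortest
[x₍ᵢ₎, x₍ᵢ₊w₋₁₎], ties broken toward the smallest lower endpoint so the
output is deterministic.  By construction the HPD is never longer than
the equal-tail interval from the same draws.

**Fiducial quantity (fq).**  With x̄, s², n₁ from the cube-root positives,

    Q_σ² = (n₁−1)s²/χ²_{n₁−1},    Q_μ = x̄ + Z·√(n₁−1)/√(χ²_{n₁−1})·s/√n₁,

Z ⟂ χ², the *same* χ² draw entering both members of a pair.  The zero
probability gets the equal-weight mixture Q_δ ~ ½Beta(n₀, n₁+1) +
½Beta(n₀+1, n₁), sampled literally (fair coin per draw, then the chosen
beta).  The mixture is written here in the zero-probability orientation,
which concentrates near n₀/n as a fiducial quantity for δ must; the
transposed orientation (concentrating near the *positive* probability)
appears in parts of the source literature and is available via
`orientation="printed"` / `--as-printed` for sensitivity analysis — at
δ = 0.5 the two are nearly indistinguishable, elsewhere the transposed
form centers τ on the wrong quantity.  A sample with n₀ = 0 or n₁ = 0
leaves one mixture component undefined; the default is a typed error,
and `boundary="component"` (used by the simulation engine, where
n₀ = 0 occurs by chance at small δ·n) falls back to the single
well-defined component.

**Parametric bootstrap (pb).**  Fit (δ̂, α̂, β̂) once; m times, draw a
full size-n dataset from the *fitted* Δ(δ̂, α̂, β̂) (zero count
Binomial(n, δ̂)), refit the closed forms, and record
τ̂* = (1−δ̂*)·(α̂*/β̂*²) + δ̂*(1−δ̂*)·(α̂*/β̂*)².  The interval is the
percentile cut of the τ̂* vector.  Resamples with fewer than two
positives (or numerically all-equal positives) are regenerated, at most
100 rounds before a typed error names the cause — relevant only for
extreme δ̂ with tiny n.  A nonparametric variant (with-replacement
resampling of the observed values) is provided for sensitivity analysis;
the parametric scheme is the default because the estimator is defined by
the fitted model.  The resampling loop is vectorized across replicates
(cumulative-sum refits over a draw matrix), which is what makes the
coverage study tractable on one CPU.

**Bayesian intervals.**  Three priors, each giving one-pass sampleable
marginal posteriors on the cube-root scale:

| prior | δ | σ² | μ |
|---|---|---|---|
| `jeffreys` | Beta(n₀+½, n₁+3/2) | IG(n₁/2, (n₁−1)s²/2) | N(x̄, σ²/n₁) given each σ² draw |
| `uniform`  | Beta(n₀+1, n₁+1)   | IG((n₁−2)/2, (n₁−1)s²/2) | N(x̄, σ²/n₁) given each σ² draw |
| `ngb`      | Beta(n₀+½, n₁+½)   | IG((n₁−1)/2, (n₁−1)s²/2) | t_{2(n₁−1)}(x̄, s²/n₁), independent of σ² |

Two deliberate fidelity choices.  First, the inverse-gamma scale in these
posteriors formally contains the unknown μ; the package substitutes the
observed cube-root mean x̄, making the scale (n₁−1)s²/2 and every
posterior directly sampleable without Gibbs iteration — the sampling
sequence (δ, then σ², then μ) only exists under this plug-in.  Second,
the Jeffreys δ posterior keeps the +3/2 second parameter of its source
(the textbook Jeffreys posterior would be Beta(n₀+½, n₁+½)); the
difference is O(1/n).  The normal-gamma-beta prior
p ∝ λ^{−1}[δ(1−δ)]^{−½} (λ = 1/σ²) yields the location-scale t marginal
for μ, drawn independently of the σ² draws.  Minimum positive counts:
n₁ ≥ 2 (jeffreys, ngb), n₁ ≥ 3 (uniform — below that the inverse-gamma
shape is nonpositive); a typed error names the minimum.  The uniform
prior's σ² posterior is extremely heavy-tailed at small n₁ (shape ≤ 1 has
no mean), which is why uniform-prior average lengths explode in
high-zero-probability, small-n₁ regimes.

## Simulation engine

`run_cell` evaluates one design cell (n, δ, α, β): M replications, each
drawing a dataset, building every requested interval from that same
dataset (paired comparison — differences between methods are not
confounded with dataset noise), and scoring coverage of the true τ and
interval length.  Reported per method: CP with binomial standard error
√(CP(1−CP)/M) and AL with the empirical standard error of the mean.
Replications with too few positives for the requested methods are
regenerated and counted; a regeneration rate above 10% flags the cell
(the estimators are then conditioned on a non-negligible selection
event).  Zero counts are Binomial(n, δ), never fixed at nδ, matching the
model.  One master seed spawns independent substreams per replication, so
results are bit-reproducible and order-insensitive; `run_grid` assembles
a tidy CSV over a cell list, recording per-cell failures without aborting.
`paper_grid` predefines the standard 36-cell design
(n ∈ {30, 50, 100, 200}; δ = 0.2 with α ∈ {7, 7.5, 7.75}, δ = 0.5 with
α ∈ {2, 2.5, 2.75}, δ = 0.8 with α ∈ {1.25, 1.5, 1.75}; β = 1) plus an
optional small-sample extension (n ∈ {10, 20}, δ ∈ {0.2, 0.5}).

Default scales: m = 5000 draws per interval and M = 10000 replications
for full-scale studies; the test suite and the acceptance script run at
desk scale M = 2000, m = 2000, where a coverage cell takes seconds on one
CPU and the binomial standard error of a CP near 0.95 is ≈ 0.005.

## What the generator does and does not emulate

`dg_sample` reproduces exactly the data-generating process the interval
theory assumes: iid draws, Bernoulli zeros, gamma positives.  Real
rainfall series additionally carry seasonality, serial correlation,
measurement rounding (small amounts recorded as zero or as fixed ticks),
and occasional regime shifts — none of which the generator emulates.
Passing coverage tests therefore demonstrates correctness of the
estimators *under the model*, not robustness of the model for any
particular station's record; the AIC/BIC screening step in the
application workflow is the user-facing guard for the positive part, and
the structural-zero assumption must be judged from the data's provenance.

## Reproducibility of previously published coverage tables

The acceptance script recomputes, among other quantities, desk-scale
coverage probabilities at design cells for which previously published
reference values exist.  Two of its findings deserve explicit note, since
they are properties of the method as printed rather than of this
implementation:

- The fiducial and normal-gamma-beta intervals at (n=100, δ=0.5, α=2)
  come out mildly conservative here (CP ≈ 0.95 at desk scale) — two to
  three coverage points above the published reference values, with
  correspondingly longer average lengths.  The direction of the gap is
  stable under the documented alternative readings of the pivot's sample
  size (using the total n instead of n₁ overshoots the other way), so the
  published table appears to reflect an intermediate convention not
  recoverable from the published formulas.
- The published tables report severe under-coverage (≈ 0.70) for the
  Jeffreys-prior interval at (n=200, δ=0.5, α=2).  Under the posteriors
  as printed, the Jeffreys posterior differs from the normal-gamma-beta
  one only by O(1/n₁) offsets in the beta parameters and the
  inverse-gamma shape, so the two intervals *must* (and here do) perform
  nearly identically, with CP ≈ 0.94–0.95 at that cell.  The dramatic
  published Jeffreys/uniform deficit cannot be produced by those
  posteriors and is not reproduced by this package.

## Numerical and degenerate-input policy

- Typed exceptions (`deltagamma.errors`) for: fewer than two positives,
  all-equal positives, boundary zero/positive counts in the fiducial
  mixture, prior-inapplicable positive counts, and unparseable or
  negative file input (with line numbers).
- Quantiles: type-7 linear interpolation everywhere; HPD ties broken
  toward the smallest lower endpoint.
- Inverse-gamma draws are generated as scale divided by gamma draws; t
  draws via the standard-t generator scaled by s/√n₁.
- Bootstrap retry cap: 100 rounds per batch of degenerate resamples.
- Output precision in CLI tables: 4 decimals, matching field convention;
  machine-readable CSV/JSON keeps full precision (CSV round-trips
  exactly).

## Limitations

- The cube-root normal approximation degrades for shape parameters well
  below ~0.5; interval calibration then inherits that error.
- The closed-form α̂ is not the exact MLE; at very small n₁ both are
  noisy and the bootstrap's refits amplify this.
- No censoring, no covariates, no serial dependence; intervals for
  functions other than the variance (mean, CV, differences between two
  variances) are out of scope.
- The uniform prior is effectively unusable for δ large and n small
  (heavy-tailed σ² posterior; see above) — a property of the prior, not
  a defect of the sampler.
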