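# deltagamma

Interval estimation for the **variance of a gamma distribution with excess
zeros** (the delta-gamma model), aimed at environmental and hydrological
data — most typically monthly rainfall series in which dry months produce
exact zeros and wet months produce right-skewed positive amounts.

## The model and the estimand

A delta-gamma variable Δ(δ, α, β) is 0 with probability δ and otherwise a
gamma(α, β) variate (shape α, scale β).  Its mean and variance are

    E X   = (1 − δ)·αβ
    Var X = τ = (1 − δ)·αβ² + δ(1 − δ)·(αβ)²

τ — the **rainfall dispersion** — is the estimand of every interval method
in the package.  Eight two-sided interval estimators are provided:

| label    | construction |
|----------|--------------|
| `fq`     | fiducial quantity: normal-theory pivots for (μ, σ²) of the cube-root-transformed positives, a two-component beta mixture for δ |
| `pb`     | parametric bootstrap: resample from the fitted Δ(δ̂, α̂, β̂), refit, percentile interval of the replicated τ̂* |
| `bay-j`, `hpd-j`     | Jeffreys-prior posterior, equal-tail / HPD |
| `bay-u`, `hpd-u`     | uniform-prior posterior, equal-tail / HPD |
| `bay-ngb`, `hpd-ngb` | normal-gamma-beta-prior posterior (t marginal for μ), equal-tail / HPD |

All gamma-side methods ride on the Wilson–Hilferty cube-root
approximation: for Y ~ gamma(a, b), Y^⅓ is approximately normal with
μ = (ba)^⅓(1 − 1/9a) and σ² = b^⅔/(9a^⅓); closed-form inverse maps
recover the gamma mean a·b and variance a·b² from (μ, σ²) draws, and each
(μ, σ², δ) draw becomes a τ draw via the variance formula above.

A Monte Carlo engine (`deltagamma.simulation`) evaluates every method's
coverage probability and average length over a configurable design grid,
and an application layer (`deltagamma.application`) runs the full
real-data workflow: AIC/BIC screening of normal / lognormal / Cauchy /
gamma candidates on the positive part, closed-form delta-gamma MLEs, and
the eight intervals.

## Worked example

Analyze a rainfall-style file (one nonnegative value per line; exact
zeros significant).  Here the file holds a synthetic series of 58 values
drawn from Δ(0.5, 2, 1), so the true variance is τ = 2.0:

```text
$ deltagamma fit --input demo_rainfall.txt
# n=58  n0=29  n1=29
# delta_hat=0.5000  alpha_hat=2.4664  beta_hat=1.5873  tau_hat=1.0931
    model     aic     bic   loglik  n_used  converged
    gamma 75.8131 78.5477 -35.9066      29       True
lognormal 78.3591 81.0937 -37.1796      29       True
   normal 80.7438 83.4784 -38.3719      29       True
   cauchy 92.4293 95.1639 -44.2146      29       True
```

Half the observations are zeros (`delta_hat=0.5000`), the gamma model
fits the positive part best (lowest AIC/BIC), and the plug-in point
estimate of the variance is `tau_hat=1.0931` (β̂ is reported as a rate,
α̂/x̄).  Then:

```text
$ deltagamma ci --input demo_rainfall.txt --method all --draws 5000 --seed 1
# deltagamma ci  level=0.95  draws=5000  seed=1
# n=58  n0=29  n1=29  mean(positives)=1.5538
# delta_hat=0.5000  alpha_hat=2.4664  beta_hat=1.5873  tau_hat=1.0931
 method     flavor  lower  upper  length
     fq equal-tail 0.6743 1.9962  1.3220
     pb equal-tail 0.6016 1.8075  1.2059
  bay-j equal-tail 0.6803 1.9661  1.2857
  hpd-j        hpd 0.6084 1.7830  1.1745
  bay-u equal-tail 0.6836 2.1485  1.4649
  hpd-u        hpd 0.6079 1.8956  1.2876
bay-ngb equal-tail 0.6528 1.9258  1.2730
hpd-ngb        hpd 0.6149 1.8323  1.2175
```

Every 95% interval brackets the plug-in τ̂ = 1.093.  This particular
draw under-disperses: the true τ = 2 lies just above most of the upper
endpoints (only the uniform-prior interval reaches it), a reminder that a
single n = 58 sample carries limited information about a variance.  HPD
intervals are never longer than their equal-tail counterparts.

The same functionality is available as a library:

```python
from deltagamma import analyze
report = analyze("demo_rainfall.txt", level=0.95, m=5000, seed=1)
print(report.intervals_frame())
```

Coverage studies run from the CLI too:

```sh
deltagamma simulate --n 100 --delta 0.5 --alpha 2 --reps 2000 --draws 2000 \
    --seed 1 --methods fq,bay-ngb --out cell.csv
deltagamma simulate --grid paper --reps 10000 --draws 5000 --seed 1 --out grid.csv
```

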