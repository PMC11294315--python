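# sltbeta

Beta-regression modelling of delay-discounting indifference points, with a
scale-location-truncated (SLT) beta likelihood that accommodates observed
values of exactly 0 and 1.

## The problem

In a delay-discounting task, a subject's *indifference point* at delay *D*
is the fraction of a larger-later reward *A* they would accept immediately
instead — someone equally happy with \$87 today or \$100 in a week has an
indifference point of 0.87 at one week. Dividing by *A* bounds every
observation in [0, 1], and the canonical hyperbolic model describes how the
expected indifference point falls with delay:

    E(y) = 1 / (1 + k·D)

where *k* > 0 is the subject's discounting rate (estimated on the log scale,
ψ = ln *k*). The standard fitting approach, nonlinear least squares (NLS),
implicitly assumes normal residuals with constant variance — a distribution
that puts probability mass outside [0, 1] and misses the characteristic
pattern of indifference-point variability (small near the 0/1 boundaries,
large mid-range). Simulating from that implied model produces "indifference
points" below 0 or above 1, which no real task can yield.

## The model

`sltbeta` instead treats each subject's points as beta-distributed in the
mean/precision parameterization: y<sub>ij</sub> ~ Beta(μ<sub>ij</sub>φ<sub>i</sub>, (1−μ<sub>ij</sub>)φ<sub>i</sub>) with
μ<sub>ij</sub> = 1/(1 + k<sub>i</sub>D<sub>j</sub>), so Var(y) = μ(1−μ)/(1+φ) — variance that
automatically shrinks toward the boundaries and peaks where μ crosses ½.

The plain beta density is zero at 0 and 1, so its likelihood is undefined
for subjects who hit the endpoints — and some do. The SLT construction maps
the observable range [0, 1] linearly onto an interior interval
[*l*, 1/*s* + *l*] of the beta support (here parameterized by a half-margin
ε: *l* = ε, *s* = 1/(1 − 2ε)) and uses the beta density *truncated* to that
interval. The resulting law has positive density at 0 and 1 yet is
numerically indistinguishable from the plain beta elsewhere for small ε
(default 1e−4). Per subject, (ψ, φ) are estimated by maximizing the SLT
log-likelihood; the classical NLS fitter is provided alongside for
comparison, and a Monte Carlo study quantifies how often each generative
model produces impossible data.

## Worked example

```python
import numpy as np
import sltbeta as sb

delays = np.array([7.0, 30.0, 90.0, 180.0, 365.0, 1095.0, 3650.0])  # days
values = np.array([1.0, 0.94, 0.71, 0.56, 0.31, 0.14, 0.0])          # y = amount / A
series = sb.IndifferencePointSeries("P01", delays, values)

slt = sb.fit_slt_beta(series)     # SLTBetaRegression(series).fit()
print(slt.summary())
nls = sb.fit_nls(series)
print(f"NLS  psi_hat = {nls.psi_hat:.4f}  k_hat = {nls.k_hat:.5f}")
```

```
=======================================
Subject fit                 P01
Method:                     slt_beta
No. indifference points:    7
psi_hat = ln(k_hat):        -5.281335
k_hat:                       0.00508564
phi_hat (precision):         7.58122
Log-likelihood:              16.961447
Converged:                  True
=======================================
NLS  psi_hat = -5.3334  k_hat = 0.00483
```

This subject has indifference points of exactly 1 (no discounting at one
week) and exactly 0 (complete discounting at ten years); the SLT likelihood
handles both, the plain beta cannot, and the two rate estimates agree with
NLS to within a few percent on the log scale (k is in units of 1/day
because the delays were given in days). The model-implied variance profile
`slt.per_delay_variance` rises from 0.0039 at the shortest delay to 0.0291
mid-range and falls to 0.0057 at the longest — the boundary-squeezed
pattern a constant NLS variance (here 0.0020 everywhere) cannot express.

The same pipeline runs from the shell:

```sh
sltbeta synth --n 146 --seed 1 --out cohort.csv
sltbeta screen --input cohort.csv --out screening.csv
sltbeta fit --input cohort.csv --method both --out fits.csv
sltbeta mc-study --fits fits.csv --generator normal --reps 1000 --seed 2 --out mc_normal.json
sltbeta report --fits fits.csv --screening screening.csv --mc mc_normal.json
```

`synth` draws a synthetic cohort (7 delays per subject, ln k ~
Normal(−4.9, 1.8²), about a quarter of subjects exhibiting an exact 0 or 1);
`screen` applies the Johnson–Bickel criteria for systematic discounting;
`fit` estimates every subject's rate by NLS and SLT beta regression;
`mc-study` counts simulated points outside [0, 1] over 1000 replications;
`report` renders the ln(k) summary table, NLS-vs-SLT scatter, and
invalid-proportion panels.

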