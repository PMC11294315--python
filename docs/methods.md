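# Methods

## Model

An indifference point at delay D, normalized by the larger-later amount A,
is modelled as a draw from a beta distribution in the mean/precision
parameterization: y ~ Beta(μφ, (1−μ)φ), with the mean tied to a discounting
curve. The default curve is hyperbolic, μ(D) = 1/(1 + kD), fitted in the
unconstrained coordinate ψ = ln k; exponential exp(−kD) and fixed-exponent
hyperboloid (1 + kD)^(−s) curves are registered as extras and share the
same fitting machinery (the hyperboloid's exponent is fixed at construction
so every fitter sees a single free rate parameter). The implied variance
μ(1−μ)/(1+φ) is a parabola in μ: variance is small where the curve hugs a
boundary (short delays near 1, long delays near 0) and largest where μ
crosses ½ — the heteroscedasticity pattern empirical indifference points
show and a constant-variance normal model cannot express.

## The scale-location truncation

The beta density vanishes at 0 and 1, so the plain beta likelihood is
undefined for subjects with endpoint observations. The SLT law maps the
observable range [0, 1] linearly onto an interior interval of the beta
support, z = y/s + l, and uses the Beta(μφ, (1−μ)φ) density truncated to
[l, 1/s + l]. Because the interval sits strictly inside (0, 1), the
truncated density is positive at its own endpoints, and hence the law of
y = s(z − l) has positive, finite density at 0 and 1.

(s, l) are parameterized by a single half-margin ε ∈ (0, 0.5): l = ε,
s = 1/(1 − 2ε), so [0, 1] maps symmetrically onto [ε, 1 − ε]. The symmetric
margin is the minimal choice that preserves the vanilla-beta limit as
ε → 0; nothing in the machinery requires symmetry, and ε is exposed
everywhere (default 1e−4, CLI `--eps`). Below ε = 1e−12 the interval
arithmetic itself is at the edge of double precision and the constructor
refuses.

The log-density is

    ln f(y) = ln Γ(φ) − ln Γ(μφ) − ln Γ((1−μ)φ)
            + (μφ − 1) ln z + ((1−μ)φ − 1) ln(1 − z)
            − ln[F(1/s + l) − F(l)] − ln s,          z = y/s + l,

with F the Beta(μφ, (1−μ)φ) CDF. The Jacobian constant −ln s is included
by default so the density integrates to one; `include_jacobian=False`
drops it, matching likelihood conventions that discard constants (it is
independent of ψ and φ and cannot move the MLE). The kernel signs are the
standard beta signs — with a flipped sign on the (μφ − 1) ln z term the
function would not normalize.

Numerical choices: all gamma-function terms are computed with `gammaln`;
the truncation mass is a difference of regularized incomplete beta
functions with an explicit error (`NumericalDegeneracyError`) if it
underflows, never a silent −inf. CDF and quantile use `betainc` /
`betaincinv`; sampling is inverse-CDF on a uniform draw restricted to
(F(l), F(1/s + l)), with results clipped into [0, 1] to absorb the last
ulp of the inverse map. Two documented precision limits: the CDF saturates
to 0/1 in double precision where a tail carries less than ~1e−16 of mass,
so the quantile/CDF round-trip identity holds only away from saturation;
and the vanilla-beta limit is slow when a beta shape is below 1 — the
density's integrable singularity puts ε^min(α,β) of mass inside the margin,
so at ε = 1e−6 with α ≈ 0.2 the truncated and plain laws (and their MLEs)
still differ noticeably. Interior-data agreement claims therefore apply to
series whose shapes stay above 1.

## Estimation

Each subject is fitted independently.

* **NLS** minimizes the sum of squared residuals over ψ via a 201-point
  coarse grid on ψ ∈ [−25, 10] followed by bounded scalar refinement; the
  grid guarantees the returned optimum is the best value seen. The residual
  variance estimator divides by (d − 1), d the number of delays. A series
  with no measurable discounting (e.g. all points at 1) drives ψ to the
  search bound; such fits are returned flagged (`at_boundary`,
  `converged=False`), never silently.
* **SLT beta / plain beta MLE** maximize the likelihood jointly over
  (ψ, τ = ln φ) with L-BFGS-B from a 3 × 3 multi-start grid — ψ₀ from the
  NLS fit and offsets {0, ±1} in each coordinate — guarding against the
  mild multimodality the likelihood can show at d = 7. φ₀ inverts the
  variance function at the mean squared NLS residual, clipped to
  [0.5, 500]. Finite-difference gradient noise limits L-BFGS-B to roughly
  1e−3 in the parameters, so the best start is polished with a bounded
  Nelder–Mead pass (xatol 1e−9); this is what makes the SLT(ε = 1e−6) and
  plain-beta estimates agree to 1e−3 on interior data. Convergence
  tolerance 1e−8 on the objective, 500 iterations per start; all knobs
  live in `OptimizerConfig`.
* The plain beta fitter refuses series containing an exact 0 or 1 at
  construction — that limitation is the SLT law's reason to exist.

No standard errors or confidence intervals are reported for ψ̂, and there
is no pooling across subjects; a hierarchical extension is out of scope.

## Screening

The Johnson–Bickel screen flags nonsystematic series: C1 is violated when
any consecutive rise exceeds 0.2 (20% of A), C2 when the first-to-last
drop is below 0.1. Violation uses strict inequality by default
(configurable to weak); both thresholds are parameters. C1 compares
consecutive delays only, in ascending order, so the screen depends only on
the ordering of delays, not their values.

## Simulation and the invalid-point study

Two generators mirror the two modelling assumptions. The normal generator
draws y ~ Normal(1/(1 + kD), σ²) and deliberately leaves draws unclipped:
the study's purpose is to count how often the NLS-implied model produces
values no task can produce. The beta generator draws from
Beta(μφ, (1−μ)φ) and cannot leave (0, 1). A point is invalid when y > 1 or
y < 0 strictly; exact endpoints are valid observations. The Monte Carlo
study regenerates a fitted cohort 1000 times (default) and tallies invalid
points overall, per delay, and per simulated subject; one master seed
spawns a substream per replication so tallies are independent of any
parallelization of the loop.

## The synthetic cohort generator

`generate_synthetic_cohort` emulates the structure of real monetary-choice
data: 7 delays per subject, per-subject ψ ~ Normal(−4.9, 1.8²) (means and
spreads typical of ln k in adult cohorts), ln φ ~ Normal(ln 20, 0.5²) (a
precision law chosen to give realistic mid-range scatter of roughly
±0.1–0.15, since task data pin down no canonical φ), and a
Bernoulli(34/146) flag for boundary-exhibiting subjects. The default delay
grid — 1 day, 1 week, 1 month, 6 months, 1 year, 5 years, 25 years —
spans the range over which a median subject's curve falls from ≈ 0.99 to
≈ 0.01; it is a property of the generator only and is nowhere assumed by
the fitters.

Unflagged subjects are sampled from the truncated SLT law, which keeps
values inside [0, 1] with exact endpoints essentially absent. Flagged
subjects are sampled through the untruncated beta with a wider margin
(ε = 0.08) and endpoint snapping — z ≤ l maps to exactly 0 and
z ≥ 1/s + l to exactly 1, the inverse-transform picture of the endpoint
mass; if a flagged subject's draws happen to all land interior, the delay
with the most extreme mean is set to its nearest boundary so the flag is
honored deterministically. The generator therefore reproduces the
qualitative composition of real cohorts (a minority of subjects with exact
0/1 points, heavy-tailed k heterogeneity) but not their nonsystematic
responders: almost every synthetic subject passes the Johnson–Bickel
screen, whereas real cohorts lose 10–15% to it. Passing tests on synthetic
cohorts consequently demonstrates correctness of the machinery under the
stated generative laws, not robustness to the full range of human response
patterns.

## Problem sizes

The test suite and the acceptance script run at the scales the analyses
are designed for: 146-subject cohorts with 7 delays, 1000 Monte Carlo
replications, 200 subjects per cell of the 3 × 3 (ψ*, φ*) recovery grid,
100-subject method-agreement cohorts, and 1e5-replication tail checks
against closed-form normal probabilities. Quartiles in the ln(k) summary
use linear interpolation; sample SDs use ddof = 1.
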