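"""The scale-location-truncated (SLT) beta distribution.

A Beta(mu*phi, (1-mu)*phi) random variable in the Ferrari–Cribari-Neto
mean/precision parameterization has density zero outside (0, 1), so a
likelihood built on it is undefined when an indifference point is exactly
0 or 1.  The SLT construction maps the observable range [0, 1] linearly
onto an interior interval [l, 1/s + l] of the beta support,

    z = y / s + l,       y = s * (z - l),

and uses the beta density *truncated* to that interval.  Because the
interval sits strictly inside (0, 1), the truncated density is positive
at both of its endpoints — hence the SLT law assigns positive density to
observed values of exactly 0 and 1 while remaining virtually
indistinguishable from the plain beta elsewhere once the interval is
nearly all of (0, 1).

Here (s, l) are parameterized by a single half-margin eps in (0, 0.5):

    l = eps,   s = 1 / (1 - 2*eps),

so [0, 1] maps symmetrically onto [eps, 1 - eps].  The default
eps = 1e-4 keeps the law numerically indistinguishable from the plain
beta on interior data.

Under the mean/precision parameterization the (untruncated) variance is
mu*(1-mu)/(1+phi): with the mean tied to a discounting curve, variance
shrinks automatically near the 0/1 boundaries and peaks mid-range, the
delay-dependent heteroscedasticity real indifference points show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .exceptions import NumericalDegeneracyError, ValidationError

DEFAULT_EPS = 1e-4

# below this the truncation-interval arithmetic 1 - 2*eps is itself
# at the edge of double precision; refuse rather than return noise
_MIN_EPS = 1e-12


def eps_to_scale_location(eps: float) -> tuple[float, float]:
    """Map the half-margin eps to the (s, l) scale/location constants."""
    if not np.isfinite(eps) or not (0.0 < eps < 0.5):
        raise ValidationError(f"eps must lie in (0, 0.5), got {eps!r}")
    if eps < _MIN_EPS:
        raise NumericalDegeneracyError(
            f"eps={eps!r} is below the numerically supported minimum {_MIN_EPS}"
        )
    return 1.0 / (1.0 - 2.0 * eps), eps


@dataclass(frozen=True)
class SltBetaParams:
    """Parameters of one SLT beta law.

    mu : mean parameter in (0, 1)
    phi : precision > 0
    s, l : scale/location constants; the observable [0, 1] maps to
        [l, 1/s + l], which must sit strictly inside (0, 1)

    Derived beta shapes are alpha = mu*phi and beta_shape = (1-mu)*phi.
    """

    mu: float
    phi: float
    s: float
    l: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and 0.0 < self.mu < 1.0):
            raise ValidationError(f"mu must be in (0, 1), got {self.mu!r}")
        if not (np.isfinite(self.phi) and self.phi > 0.0):
            raise ValidationError(f"phi must be positive, got {self.phi!r}")
        if not (np.isfinite(self.s) and self.s > 1.0):
            raise ValidationError(f"scale s must exceed 1, got {self.s!r}")
        if not (0.0 < self.l and self.l + 1.0 / self.s < 1.0):
            raise ValidationError(
                f"location l={self.l!r} with s={self.s!r} must satisfy 0 < l < l + 1/s < 1"
            )

    @classmethod
    def from_eps(cls, mu: float, phi: float, eps: float = DEFAULT_EPS) -> "SltBetaParams":
        s, l = eps_to_scale_location(eps)
        return cls(mu=mu, phi=phi, s=s, l=l)

    @property
    def alpha(self) -> float:
        return self.mu * self.phi

    @property
    def beta_shape(self) -> float:
        return (1.0 - self.mu) * self.phi

    @property
    def upper(self) -> float:
        """Upper end of the mapped interval, 1/s + l."""
        return 1.0 / self.s + self.l


def slt_transform(y, s: float, l: float):
    """Map observable y in [0, 1] to the interior point z = y/s + l."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1) | ~np.isfinite(y)):
        raise ValidationError("y must lie in [0, 1]")
    out = y / s + l
    return float(out) if out.ndim == 0 else out


def slt_inverse_transform(z, s: float, l: float):
    """Inverse map y = s*(z - l); exact endpoints recover 0 and 1."""
    z = np.asarray(z, dtype=float)
    out = s * (z - l)
    return float(out) if out.ndim == 0 else out


def _log_trunc_mass(a: float, b: float, l: float, u: float) -> float:
    """log of F(u) - F(l) for F the Beta(a, b) CDF, with underflow guard."""
    mass = special.betainc(a, b, u) - special.betainc(a, b, l)
    if not np.isfinite(mass) or mass <= 0.0:
        raise NumericalDegeneracyError(
            f"truncation mass vanished for shapes ({a:g}, {b:g}) on [{l:g}, {u:g}]"
        )
    return float(np.log(mass))


def beta_variance(mu: float, phi: float):
    """Variance of the mean/precision beta: mu*(1-mu)/(1+phi).

    Accepts arrays in either argument; boundary mu of 0 or 1 gives 0.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((mu < 0) | (mu > 1) | ~np.isfinite(mu)):
        raise ValidationError("mu must lie in [0, 1]")
    if np.any(phi <= 0):
        raise ValidationError("phi must be positive")
    out = mu * (1.0 - mu) / (1.0 + phi)
    return float(out) if out.ndim == 0 else out


def slt_log_pdf(y, params: SltBetaParams, include_jacobian: bool = True):
    """Log-density of the SLT beta law at y in [0, 1]; finite at 0 and 1.

    The density of y is the Beta(alpha, beta) density evaluated at
    z = y/s + l, renormalized by the truncation mass F(1/s+l) - F(l),
    times the Jacobian 1/s of the linear map.  ``include_jacobian=False``
    drops the constant -ln(s) term, matching likelihood conventions that
    discard constants (it cannot affect maximum-likelihood estimates).

    All gamma-function quantities are computed on the log scale.
    """
    a, b = params.alpha, params.beta_shape
    z = slt_transform(y, params.s, params.l)
    z = np.asarray(z, dtype=float)
    log_kernel = (
        special.gammaln(params.phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(z)
        + (b - 1.0) * np.log1p(-z)
    )
    out = log_kernel - _log_trunc_mass(a, b, params.l, params.upper)
    if include_jacobian:
        out = out - np.log(params.s)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def slt_cdf(y, params: SltBetaParams):
    """CDF of the SLT beta law: (F(y/s+l) - F(l)) / (F(1/s+l) - F(l))."""
    a, b = params.alpha, params.beta_shape
    z = np.asarray(slt_transform(y, params.s, params.l), dtype=float)
    lo = special.betainc(a, b, params.l)
    hi = special.betainc(a, b, params.upper)
    mass = hi - lo
    if not np.isfinite(mass) or mass <= 0.0:
        raise NumericalDegeneracyError(
            f"truncation mass vanished for shapes ({a:g}, {b:g})"
        )
    out = np.clip((special.betainc(a, b, z) - lo) / mass, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def slt_quantile(p, params: SltBetaParams):
    """Quantile (inverse CDF) of the SLT beta law; returns values in [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p must lie in [0, 1]")
    a, b = params.alpha, params.beta_shape
    lo = special.betainc(a, b, params.l)
    hi = special.betainc(a, b, params.upper)
    if not np.isfinite(hi - lo) or hi - lo <= 0.0:
        raise NumericalDegeneracyError(
            f"truncation mass vanished for shapes ({a:g}, {b:g})"
        )
    z = special.betaincinv(a, b, lo + p * (hi - lo))
    y = np.clip(slt_inverse_transform(z, params.s, params.l), 0.0, 1.0)
    out = np.asarray(y)
    return float(out) if out.ndim == 0 else out


def slt_sample(params: SltBetaParams, n: int, rng=None) -> np.ndarray:
    """Draw n values from the SLT beta law by inverse-CDF sampling.

    ``rng`` is a :class:`numpy.random.Generator`, a seed, or None.
    All outputs lie in [0, 1] and are reproducible given a seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return np.asarray(slt_quantile(rng.uniform(size=int(n)), params), dtype=float)


def slt_loglik(values: np.ndarray, mus: np.ndarray, phi: float, eps: float,
               include_jacobian: bool = False) -> float:
    """Sum of SLT log-densities with a per-observation mean vector.

    Vectorized core used by the regression fitters: observation j has its
    own mean mu_j (from the discounting curve) and shared precision phi.
    The Jacobian constant is omitted by default (likelihood convention).
    """
    s, l = eps_to_scale_location(eps)
    mus = np.asarray(mus, dtype=float)
    values = np.asarray(values, dtype=float)
    a = mus * phi
    b = (1.0 - mus) * phi
    upper = 1.0 / s + l
    z = values / s + l
    mass = special.betainc(a, b, upper) - special.betainc(a, b, l)
    if np.any(~np.isfinite(mass) | (mass <= 0.0)):
        raise NumericalDegeneracyError("truncation mass vanished for some observation")
    ll = (
        special.gammaln(phi) * values.size
        - np.sum(special.gammaln(a))
        - np.sum(special.gammaln(b))
        + np.sum((a - 1.0) * np.log(z))
        + np.sum((b - 1.0) * np.log1p(-z))
        - np.sum(np.log(mass))
    )
    if include_jacobian:
        ll -= values.size * np.log(s)
    return float(ll)


def beta_loglik(values: np.ndarray, mus: np.ndarray, phi: float) -> float:
    """Plain (untruncated) beta log-likelihood; -inf is impossible because
    callers must guarantee values strictly inside (0, 1)."""
    values = np.asarray(values, dtype=float)
    if np.any((values <= 0.0) | (values >= 1.0)):
        raise ValidationError("plain beta likelihood requires values strictly inside (0, 1)")
    mus = np.asarray(mus, dtype=float)
    a = mus * phi
    b = (1.0 - mus) * phi
    return float(
        special.gammaln(phi) * values.size
        - np.sum(special.gammaln(a))
        - np.sum(special.gammaln(b))
        + np.sum((a - 1.0) * np.log(values))
        + np.sum((b - 1.0) * np.log1p(-values))
    )
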