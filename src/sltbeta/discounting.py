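"""Discounting mean functions E(y) as functions of delay.

The workhorse is the single-parameter hyperbolic curve

    E(y) = 1 / (1 + k * D)

with discounting rate k > 0 estimated on the log scale, psi = ln(k),
so that optimization is unconstrained.  The registry is extensible;
exponential and (fixed-exponent) hyperboloid curves are provided as
extras beyond the hyperbolic model the analyses here exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import ValidationError


def hyperbolic_mean(k: float, delay) -> np.ndarray | float:
    """Hyperbolic discounting curve 1/(1 + k*delay); value in (0, 1]."""
    if not np.isfinite(k) or k <= 0:
        raise ValidationError(f"discounting rate k must be positive, got {k!r}")
    delay = np.asarray(delay, dtype=float)
    if np.any(delay < 0):
        raise ValidationError("delay must be nonnegative")
    out = 1.0 / (1.0 + k * delay)
    return float(out) if out.ndim == 0 else out


def mean_from_psi(psi: float, delay) -> np.ndarray | float:
    """Hyperbolic mean in the psi = ln(k) parameterization: 1/(1 + exp(psi)*delay)."""
    if not np.isfinite(psi):
        raise ValidationError(f"psi must be finite, got {psi!r}")
    delay = np.asarray(delay, dtype=float)
    if np.any(delay < 0):
        raise ValidationError("delay must be nonnegative")
    out = 1.0 / (1.0 + np.exp(psi) * delay)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DiscountingModel:
    """A named mean function with its natural/unconstrained parameter maps.

    ``mean_psi(psi, delays)`` evaluates the curve in the unconstrained
    log-rate coordinate used by every fitter; ``mean(k, delays)`` in the
    natural rate coordinate.  For all registered models the curve equals 1
    at delay 0, is strictly decreasing in delay for k > 0, and stays in
    (0, 1] — the invariants the beta-mean link relies on.
    """

    name: str
    _mean_psi: Callable[[float, np.ndarray], np.ndarray]
    n_params: int = 1

    def mean_psi(self, psi: float, delay) -> np.ndarray | float:
        if not np.isfinite(psi):
            raise ValidationError(f"psi must be finite, got {psi!r}")
        delay = np.asarray(delay, dtype=float)
        if np.any(delay < 0):
            raise ValidationError("delay must be nonnegative")
        out = np.asarray(self._mean_psi(psi, delay), dtype=float)
        return float(out) if out.ndim == 0 else out

    def mean(self, k: float, delay) -> np.ndarray | float:
        if not np.isfinite(k) or k <= 0:
            raise ValidationError(f"discounting rate k must be positive, got {k!r}")
        return self.mean_psi(float(np.log(k)), delay)

    @staticmethod
    def to_unconstrained(k: float) -> float:
        return float(np.log(k))

    @staticmethod
    def from_unconstrained(psi: float) -> float:
        return float(np.exp(psi))


_REGISTRY: dict[str, Callable[..., DiscountingModel]] = {}


def register_model(name: str, factory: Callable[..., DiscountingModel]) -> None:
    _REGISTRY[name] = factory


def get_model(name: str | DiscountingModel = "hyperbolic", **kwargs) -> DiscountingModel:
    """Look a discounting model up by name (passes a model through unchanged)."""
    if isinstance(name, DiscountingModel):
        return name
    try:
        return _REGISTRY[name](**kwargs)
    except KeyError:
        raise ValidationError(
            f"unknown discounting model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


register_model(
    "hyperbolic",
    lambda: DiscountingModel("hyperbolic", lambda psi, D: 1.0 / (1.0 + np.exp(psi) * D)),
)
register_model(
    "exponential",
    lambda: DiscountingModel("exponential", lambda psi, D: np.exp(-np.exp(psi) * D)),
)


def _hyperboloid(exponent: float = 2.0) -> DiscountingModel:
    # exponent fixed at construction so the fitters keep a single free rate
    if exponent <= 0:
        raise ValidationError("hyperboloid exponent must be positive")
    return DiscountingModel(
        f"hyperboloid(s={exponent:g})",
        lambda psi, D: (1.0 + np.exp(psi) * D) ** (-exponent),
    )


register_model("hyperboloid", _hyperboloid)
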