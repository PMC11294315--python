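"""Per-subject estimation of the discounting rate.

Three estimators share one statsmodels-flavoured interface — a model object
built from one subject's :class:`~sltbeta.data.IndifferencePointSeries`,
whose ``fit()`` returns a :class:`SubjectFit` results object:

``NLSDiscounting``
    Nonlinear least squares: psi_hat minimizes the sum of squared
    residuals; the residual variance sigma2_hat uses divisor (d - 1).
``SLTBetaRegression``
    Joint maximum likelihood of (psi, phi) under the scale-location-
    truncated beta law, which accommodates observed 0s and 1s.
``BetaRegression``
    Maximum likelihood under the plain beta law; raises when the series
    contains an exact 0 or 1 (the documented limitation the SLT
    construction removes).

All optimization runs in unconstrained coordinates (psi = ln k,
tau = ln phi) with multi-start to guard against the mild multimodality
the likelihood can show at small numbers of delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Cohort, IndifferencePointSeries
from .discounting import DiscountingModel, get_model
from .distribution import (
    DEFAULT_EPS,
    beta_loglik,
    beta_variance,
    slt_loglik,
)
from .exceptions import ValidationError

PSI_BOUNDS = (-25.0, 10.0)
TAU_BOUNDS = (-5.0, 10.0)  # phi in [exp(-5), exp(10)] ~ [6.7e-3, 2.2e4]


@dataclass
class OptimizerConfig:
    """Knobs for the likelihood/least-squares optimizers.

    tol is the convergence tolerance on the objective; psi_offsets and
    tau_offsets define the multi-start grid around the initial values.
    """

    tol: float = 1e-8
    max_iter: int = 500
    psi_bounds: tuple[float, float] = PSI_BOUNDS
    tau_bounds: tuple[float, float] = TAU_BOUNDS
    psi_offsets: tuple[float, ...] = (0.0, -1.0, 1.0)
    tau_offsets: tuple[float, ...] = (0.0, -1.0, 1.0)
    phi_init_clip: tuple[float, float] = (0.5, 500.0)


@dataclass
class SubjectFit:
    """Estimation result for one subject under one method.

    psi_hat is the estimated ln(k); k_hat = exp(psi_hat) is in reciprocal
    units of the subject's delays.  Beta methods carry phi_hat and the
    maximized log_likelihood; NLS carries sigma2_hat (divisor d - 1) and
    the minimized sse.  ``at_boundary`` flags estimates pinned at the
    search bounds (e.g. a subject who never discounts), which are
    reported rather than silently returned as interior optima.
    """

    subject_id: str
    method: str
    psi_hat: float
    phi_hat: float | None = None
    sigma2_hat: float | None = None
    log_likelihood: float | None = None
    sse: float | None = None
    converged: bool = True
    at_boundary: bool = False
    message: str = ""
    n_points: int = 0
    delays: np.ndarray = field(default_factory=lambda: np.empty(0))
    fitted_means: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k_hat(self) -> float:
        return float(np.exp(self.psi_hat))

    @property
    def per_delay_variance(self) -> np.ndarray:
        return variance_profile(self)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"{'Subject fit':<28}{self.subject_id}",
            f"{'Method:':<28}{self.method}",
            f"{'No. indifference points:':<28}{self.n_points}",
            f"{'psi_hat = ln(k_hat):':<28}{self.psi_hat: .6f}",
            f"{'k_hat:':<28}{self.k_hat: .6g}",
        ]
        if self.phi_hat is not None:
            lines.append(f"{'phi_hat (precision):':<28}{self.phi_hat: .6g}")
        if self.sigma2_hat is not None:
            lines.append(f"{'sigma2_hat (resid var):':<28}{self.sigma2_hat: .6g}")
        if self.log_likelihood is not None:
            lines.append(f"{'Log-likelihood:':<28}{self.log_likelihood: .6f}")
        if self.sse is not None:
            lines.append(f"{'SSE:':<28}{self.sse: .6g}")
        lines.append(f"{'Converged:':<28}{self.converged}")
        if self.at_boundary:
            lines.append(f"{'At parameter bound:':<28}True")
        if self.message:
            lines.append(f"{'Note:':<28}{self.message}")
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, *lines, rule])

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "method": self.method,
            "psi_hat": self.psi_hat,
            "k_hat": self.k_hat,
            "phi_hat": self.phi_hat,
            "sigma2_hat": self.sigma2_hat,
            "log_likelihood": self.log_likelihood,
            "sse": self.sse,
            "converged": self.converged,
            "at_boundary": self.at_boundary,
            "n_points": self.n_points,
        }


def variance_profile(fit: SubjectFit) -> np.ndarray:
    """Model-implied response variance at each of the subject's delays.

    Beta methods: mu_j*(1-mu_j)/(1+phi_hat), the delay-dependent variance
    function; NLS: the constant sigma2_hat repeated once per delay.
    """
    if fit.method == "nls":
        return np.full(fit.n_points, fit.sigma2_hat, dtype=float)
    return np.asarray(beta_variance(fit.fitted_means, fit.phi_hat), dtype=float)


class _SubjectModel:
    """Shared plumbing: hold a series and a discounting model."""

    method: str = ""

    def __init__(self, series: IndifferencePointSeries, discounting="hyperbolic"):
        self.series = series
        self.model: DiscountingModel = get_model(discounting)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, subject: str | None = None, **kwargs):
        """Build from a tidy frame with subject/delay/value columns."""
        from .data import cohort_from_dataframe

        cohort = cohort_from_dataframe(df)
        if subject is not None:
            matches = [s for s in cohort if s.subject_id == str(subject)]
            if not matches:
                raise ValidationError(f"subject {subject!r} not found in frame")
            series = matches[0]
        elif len(cohort) == 1:
            series = cohort[0]
        else:
            raise ValidationError("frame contains multiple subjects; pass subject=")
        return cls(series, **kwargs)

    def _means(self, psi: float) -> np.ndarray:
        return np.asarray(self.model.mean_psi(psi, self.series.delays), dtype=float)


class NLSDiscounting(_SubjectModel):
    """Nonlinear least squares for the discounting rate.

    Minimizes sum_j (y_j - mean(psi, D_j))^2 over psi = ln(k), via a coarse
    grid followed by bounded scalar refinement; the grid guarantees the
    returned optimum is the best found.  The residual variance estimator
    uses divisor (d - 1).
    """

    method = "nls"

    def _sse(self, psi: float) -> float:
        r = self.series.values - self._means(psi)
        return float(np.dot(r, r))

    def fit(self, config: OptimizerConfig | None = None) -> SubjectFit:
        cfg = config or OptimizerConfig()
        lo, hi = cfg.psi_bounds
        grid = np.linspace(lo, hi, 201)
        sse_grid = np.array([self._sse(p) for p in grid])
        i = int(np.argmin(sse_grid))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            self._sse, bounds=(a, b), method="bounded",
            options={"xatol": 1e-10, "maxiter": cfg.max_iter},
        )
        psi_hat, sse = (float(res.x), float(res.fun))
        if sse_grid[i] < sse:  # keep the best point seen anywhere
            psi_hat, sse = float(grid[i]), float(sse_grid[i])
        at_bound = psi_hat <= lo + 1e-6 or psi_hat >= hi - 1e-6
        d = self.series.n_points
        fit = SubjectFit(
            subject_id=self.series.subject_id,
            method=self.method,
            psi_hat=psi_hat,
            sigma2_hat=sse / (d - 1),
            sse=sse,
            converged=bool(res.success) and not at_bound,
            at_boundary=at_bound,
            message="estimate at psi search bound (no measurable discounting?)" if at_bound else "",
            n_points=d,
            delays=self.series.delays.copy(),
            fitted_means=self._means(psi_hat),
        )
        return fit


class _LikelihoodModel(_SubjectModel):
    """Shared MLE machinery for the beta-family models."""

    def _loglik(self, psi: float, phi: float) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _init_values(self, cfg: OptimizerConfig) -> tuple[float, float]:
        """psi0 from NLS; phi0 by inverting the variance function on the
        mean squared NLS residual."""
        nls = NLSDiscounting(self.series, self.model).fit(cfg)
        mu0 = np.clip(nls.fitted_means, 1e-6, 1.0 - 1e-6)
        v_hat = float(np.mean((self.series.values - nls.fitted_means) ** 2))
        lo, hi = cfg.phi_init_clip
        if v_hat <= 0.0:
            phi0 = hi
        else:
            phi0 = float(np.clip(np.mean(mu0 * (1.0 - mu0) / v_hat - 1.0), lo, hi))
        return float(np.clip(nls.psi_hat, *cfg.psi_bounds)), phi0

    def fit(self, config: OptimizerConfig | None = None) -> SubjectFit:
        cfg = config or OptimizerConfig()
        psi0, phi0 = self._init_values(cfg)
        tau0 = float(np.log(phi0))

        def nll(theta: np.ndarray) -> float:
            try:
                return -self._loglik(float(theta[0]), float(np.exp(theta[1])))
            except (ValidationError, ArithmeticError):
                return np.inf

        bounds = [cfg.psi_bounds, cfg.tau_bounds]
        best = None
        n_ok = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for dpsi in cfg.psi_offsets:
                for dtau in cfg.tau_offsets:
                    x0 = np.array(
                        [
                            np.clip(psi0 + dpsi, *cfg.psi_bounds),
                            np.clip(tau0 + dtau, *cfg.tau_bounds),
                        ]
                    )
                    res = optimize.minimize(
                        nll, x0, method="L-BFGS-B", bounds=bounds,
                        options={"ftol": cfg.tol, "gtol": 1e-9, "maxiter": cfg.max_iter},
                    )
                    n_ok += bool(res.success)
                    if best is None or res.fun < best.fun:
                        best = res
            # derivative-free polish: finite-difference gradient noise limits
            # L-BFGS-B to ~1e-3 in the parameters, too coarse for the
            # vanilla-limit agreement this model family promises
            polish = optimize.minimize(
                nll, best.x, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4 * cfg.max_iter},
            )
            if polish.fun <= best.fun:
                best = polish
        psi_hat = float(best.x[0])
        phi_hat = float(np.exp(best.x[1]))
        at_bound = (
            psi_hat <= cfg.psi_bounds[0] + 1e-6
            or psi_hat >= cfg.psi_bounds[1] - 1e-6
            or best.x[1] <= cfg.tau_bounds[0] + 1e-6
            or best.x[1] >= cfg.tau_bounds[1] - 1e-6
        )
        return SubjectFit(
            subject_id=self.series.subject_id,
            method=self.method,
            psi_hat=psi_hat,
            phi_hat=phi_hat,
            log_likelihood=float(-best.fun),
            converged=n_ok > 0 and np.isfinite(best.fun) and not at_bound,
            at_boundary=at_bound,
            message="estimate at parameter bound" if at_bound else "",
            n_points=self.series.n_points,
            delays=self.series.delays.copy(),
            fitted_means=self._means(psi_hat),
        )


class SLTBetaRegression(_LikelihoodModel):
    """Maximum likelihood under the SLT beta law.

    Handles observed values of exactly 0 and 1 — the log-likelihood stays
    finite at the endpoints because the truncated beta density is positive
    there.  ``eps`` is the truncation half-margin (default 1e-4).
    """

    method = "slt_beta"

    def __init__(self, series, discounting="hyperbolic", eps: float = DEFAULT_EPS):
        super().__init__(series, discounting)
        self.eps = float(eps)

    def _loglik(self, psi: float, phi: float) -> float:
        return slt_loglik(self.series.values, self._means(psi), phi, self.eps)


class BetaRegression(_LikelihoodModel):
    """Maximum likelihood under the plain (untruncated) beta law.

    Defined only for series strictly inside (0, 1); construction fails on
    boundary data because the beta density is zero at 0 and 1.
    """

    method = "beta"

    def __init__(self, series, discounting="hyperbolic"):
        super().__init__(series, discounting)
        if np.any((series.values <= 0.0) | (series.values >= 1.0)):
            raise ValidationError(
                f"subject {series.subject_id!r}: plain beta regression cannot "
                "estimate k when the series contains an indifference point of "
                "exactly 0 or 1; use SLTBetaRegression"
            )

    def _loglik(self, psi: float, phi: float) -> float:
        return beta_loglik(self.series.values, self._means(psi), phi)


# ---------------------------------------------------------------------------
# functional conveniences


def fit_nls(series: IndifferencePointSeries, model="hyperbolic",
            config: OptimizerConfig | None = None) -> SubjectFit:
    """Nonlinear least squares fit of one subject."""
    return NLSDiscounting(series, model).fit(config)


def fit_slt_beta(series: IndifferencePointSeries, model="hyperbolic",
                 eps: float = DEFAULT_EPS,
                 config: OptimizerConfig | None = None) -> SubjectFit:
    """SLT beta maximum-likelihood fit of one subject."""
    return SLTBetaRegression(series, model, eps=eps).fit(config)


def fit_vanilla_beta(series: IndifferencePointSeries, model="hyperbolic",
                     config: OptimizerConfig | None = None) -> SubjectFit:
    """Plain beta maximum-likelihood fit (interior data only)."""
    return BetaRegression(series, model).fit(config)


_METHODS = {
    "nls": fit_nls,
    "slt": fit_slt_beta,
    "slt_beta": fit_slt_beta,
    "beta": fit_vanilla_beta,
}


def fit_cohort(cohort: Cohort, method: str = "both", model="hyperbolic",
               eps: float = DEFAULT_EPS,
               config: OptimizerConfig | None = None) -> list[SubjectFit]:
    """Fit every subject in a cohort; ``method`` in {nls, slt, beta, both}.

    ``both`` runs NLS and SLT beta on each subject.
    """
    methods = ["nls", "slt"] if method == "both" else [method]
    for m in methods:
        if m not in _METHODS:
            raise ValidationError(f"unknown method {m!r}; choose from nls, slt, beta, both")
    fits = []
    for series in cohort:
        for m in methods:
            if m in ("slt", "slt_beta"):
                fits.append(fit_slt_beta(series, model, eps=eps, config=config))
            else:
                fits.append(_METHODS[m](series, model, config=config))
    return fits


def fits_to_dataframe(fits: Iterable[SubjectFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])


def lnk_summary(values: Sequence[float]) -> dict:
    """Min/Q1/median/Q3/max/mean/SD of a vector of ln(k) estimates.

    Quartiles use linear interpolation; SD is the sample (ddof=1) SD.
    """
    v = np.asarray(values, dtype=float)
    return {
        "min": float(np.min(v)),
        "q1": float(np.quantile(v, 0.25)),
        "median": float(np.median(v)),
        "q3": float(np.quantile(v, 0.75)),
        "max": float(np.max(v)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
    }


@dataclass
class LnkComparison:
    """Paired ln(k_hat) agreement report between two estimation methods."""

    table: pd.DataFrame  # columns: subject, lnk_a, lnk_b
    summary: pd.DataFrame  # one row per method: min q1 median q3 max mean sd
    pearson_r: float

    def __str__(self) -> str:
        return (
            "ln(k) agreement\n"
            + self.summary.to_string(float_format=lambda x: f"{x: .3f}")
            + f"\nPearson r = {self.pearson_r:.4f} (n = {len(self.table)})"
        )


def compare_lnk(fits_a: Sequence[SubjectFit], fits_b: Sequence[SubjectFit]) -> LnkComparison:
    """Pair two fit sets by subject and summarize ln(k_hat) agreement.

    Requires matched subject ids and converged fits on both sides.
    """
    da = {f.subject_id: f for f in fits_a}
    db = {f.subject_id: f for f in fits_b}
    unmatched = sorted(set(da) ^ set(db))
    if unmatched:
        raise ValidationError(f"subject ids not present in both fit sets: {unmatched}")
    bad = sorted(i for i in da if not (da[i].converged and db[i].converged))
    if bad:
        raise ValidationError(f"non-converged fits for subjects: {bad}")
    ids = sorted(da)
    lnk_a = np.array([da[i].psi_hat for i in ids])
    lnk_b = np.array([db[i].psi_hat for i in ids])
    name_a = fits_a[0].method if len(fits_a) else "a"
    name_b = fits_b[0].method if len(fits_b) else "b"
    table = pd.DataFrame({"subject": ids, f"lnk_{name_a}": lnk_a, f"lnk_{name_b}": lnk_b})
    summary = pd.DataFrame(
        [lnk_summary(lnk_a), lnk_summary(lnk_b)], index=[name_a, name_b]
    )
    if np.allclose(lnk_a, lnk_b):
        r = 1.0
    else:
        r = float(stats.pearsonr(lnk_a, lnk_b).statistic)
    return LnkComparison(table=table, summary=summary, pearson_r=r)
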