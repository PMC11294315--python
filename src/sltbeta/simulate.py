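"""Simulation of indifference-point data and the Monte Carlo invalid-point study.

Two per-subject generators mirror the two modelling assumptions under
comparison:

normal
    y_j ~ Normal(1/(1 + k*D_j), sigma2) — the implicit generative model of
    ordinary nonlinear least squares.  Draws are deliberately NOT clipped:
    values outside [0, 1] are impossible for real task data, and exposing
    how often the normal model produces them is the point of the study.
beta
    y_j ~ Beta(mu_j*phi, (1-mu_j)*phi) with mu_j = 1/(1 + k*D_j) — the
    mean/precision beta model, whose support makes out-of-bounds values
    impossible by construction.

``run_mc_study`` regenerates a cohort ``n_replications`` times (default
1000) and tallies simulated points outside [0, 1] overall, per delay, and
per simulated subject.  A point is invalid when it strictly exceeds 1 or
falls strictly below 0; exact 0 and 1 are valid observations.

``generate_synthetic_cohort`` draws whole cohorts that emulate the
structure of real monetary-choice data: 7 delays per subject, per-subject
ln(k) approximately normal with mean -4.9 and SD 1.8, and a minority of
subjects exhibiting at least one exact 0 or 1 indifference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import Cohort, IndifferencePointSeries
from .discounting import hyperbolic_mean
from .distribution import SltBetaParams, eps_to_scale_location, slt_sample
from .exceptions import ValidationError
from .model import SubjectFit

#: Default delay grid for the synthetic generator only (days):
#: 1 day, 1 week, 1 month, 6 months, 1 year, 5 years, 25 years.
DEFAULT_DELAYS: tuple[float, ...] = (1.0, 7.0, 30.0, 182.5, 365.0, 1825.0, 9125.0)

#: Default fraction of subjects forced to exhibit a boundary value,
#: emulating cohorts where roughly a quarter of subjects hit 0 or 1.
DEFAULT_BOUNDARY_FRACTION: float = 34.0 / 146.0


@dataclass
class SimulationDesign:
    """Replication design for the Monte Carlo invalid-point study."""

    delays: Sequence[float] = DEFAULT_DELAYS
    n_replications: int = 1000
    seed: int | None = None
    generator: str = "beta"

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        if np.any(self.delays <= 0):
            raise ValidationError("delays must be positive")
        if self.n_replications < 1:
            raise ValidationError("n_replications must be >= 1")
        if self.generator not in ("normal", "beta"):
            raise ValidationError(f"generator must be 'normal' or 'beta', got {self.generator!r}")


@dataclass
class InvalidPointSummary:
    """Tallies of simulated points outside [0, 1].

    Proportions are over all replications: ``prop_invalid_points`` has
    denominator n_replications * n_subjects * n_delays;
    ``prop_subjects_any_invalid`` counts simulated subjects (replication x
    subject pairs) with at least one invalid point.
    """

    n_replications: int
    n_subjects: int
    n_delays: int
    n_invalid_points: int
    n_subjects_any_invalid: int
    invalid_by_delay: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_points_total(self) -> int:
        return self.n_replications * self.n_subjects * self.n_delays

    @property
    def n_subjects_total(self) -> int:
        return self.n_replications * self.n_subjects

    @property
    def prop_invalid_points(self) -> float:
        return self.n_invalid_points / self.n_points_total

    @property
    def prop_invalid_by_delay(self) -> np.ndarray:
        return self.invalid_by_delay / (self.n_replications * self.n_subjects)

    @property
    def prop_subjects_any_invalid(self) -> float:
        return self.n_subjects_any_invalid / self.n_subjects_total

    def to_dict(self) -> dict:
        return {
            "n_replications": self.n_replications,
            "n_subjects": self.n_subjects,
            "n_delays": self.n_delays,
            "n_invalid_points": int(self.n_invalid_points),
            "n_subjects_any_invalid": int(self.n_subjects_any_invalid),
            "invalid_by_delay": [int(c) for c in self.invalid_by_delay],
            "prop_invalid_points": self.prop_invalid_points,
            "prop_invalid_by_delay": [float(p) for p in self.prop_invalid_by_delay],
            "prop_subjects_any_invalid": self.prop_subjects_any_invalid,
        }


def simulate_normal_subject(k: float, sigma2: float, delays, rng=None) -> np.ndarray:
    """Draw one subject's series under the constant-variance normal model.

    Values are unclipped — out-of-bounds draws survive so they can be
    counted.  sigma2 = 0 returns the hyperbolic mean exactly.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be nonnegative")
    rng = np.random.default_rng(rng)
    mu = np.asarray(hyperbolic_mean(k, delays), dtype=float)
    if sigma2 == 0.0:
        return mu.copy()
    return rng.normal(mu, np.sqrt(sigma2))


def simulate_beta_subject(k: float, phi: float, delays, rng=None) -> np.ndarray:
    """Draw one subject's series under the mean/precision beta model.

    mu_j = 1/(1 + k*D_j), y_j ~ Beta(mu_j*phi, (1-mu_j)*phi); outputs lie
    strictly inside (0, 1).
    """
    if phi <= 0:
        raise ValidationError("phi must be positive")
    rng = np.random.default_rng(rng)
    mu = np.asarray(hyperbolic_mean(k, delays), dtype=float)
    return rng.beta(mu * phi, (1.0 - mu) * phi)


def _as_param_table(cohort_fits, generator: str) -> list[tuple[str, float, float]]:
    """Normalize fit inputs to (subject_id, k, scale) tuples.

    ``scale`` is sigma2 for the normal generator, phi for the beta one.
    Accepts SubjectFit objects or (id, k, scale) / (k, scale) tuples.
    """
    out = []
    for i, item in enumerate(cohort_fits):
        if isinstance(item, SubjectFit):
            if not item.converged:
                raise ValidationError(f"fit for subject {item.subject_id!r} did not converge")
            scale = item.sigma2_hat if generator == "normal" else item.phi_hat
            if scale is None:
                raise ValidationError(
                    f"fit for subject {item.subject_id!r} lacks the "
                    f"{'sigma2' if generator == 'normal' else 'phi'} estimate "
                    f"the {generator} generator needs"
                )
            out.append((item.subject_id, item.k_hat, float(scale)))
        else:
            tup = tuple(item)
            if len(tup) == 3:
                out.append((str(tup[0]), float(tup[1]), float(tup[2])))
            elif len(tup) == 2:
                out.append((str(i), float(tup[0]), float(tup[1])))
            else:
                raise ValidationError("expected SubjectFit or (id, k, scale) tuples")
    return out


def run_mc_study(cohort_fits, design: SimulationDesign) -> InvalidPointSummary:
    """The Monte Carlo invalid-point study.

    For each of ``design.n_replications`` replications, every subject's
    series is regenerated under ``design.generator`` from that subject's
    fitted parameters, and points outside [0, 1] are tallied overall, per
    delay, and per simulated subject.  The master seed spawns one
    substream per replication, so tallies do not depend on how the
    replication loop might be parallelized.
    """
    params = _as_param_table(cohort_fits, design.generator)
    delays = np.asarray(design.delays, dtype=float)
    d = delays.size
    n_sub = len(params)
    ks = np.array([p[1] for p in params])
    scales = np.array([p[2] for p in params])
    mus = 1.0 / (1.0 + ks[:, None] * delays[None, :])  # (n_sub, d)

    n_invalid = 0
    n_subj_any = 0
    by_delay = np.zeros(d, dtype=np.int64)
    children = np.random.SeedSequence(design.seed).spawn(design.n_replications)
    for child in children:
        rng = np.random.default_rng(child)
        if design.generator == "normal":
            y = rng.normal(mus, np.sqrt(scales)[:, None])
        else:
            y = rng.beta(mus * scales[:, None], (1.0 - mus) * scales[:, None])
        invalid = (y > 1.0) | (y < 0.0)
        n_invalid += int(invalid.sum())
        by_delay += invalid.sum(axis=0)
        n_subj_any += int(invalid.any(axis=1).sum())
    return InvalidPointSummary(
        n_replications=design.n_replications,
        n_subjects=n_sub,
        n_delays=d,
        n_invalid_points=n_invalid,
        n_subjects_any_invalid=n_subj_any,
        invalid_by_delay=by_delay,
    )


def simulate_cohort_once(cohort_fits, design: SimulationDesign) -> Cohort:
    """One replication of the designated generator as a Cohort.

    Normal-generator draws are clipped *into* [0, 1] here only because a
    Cohort cannot hold invalid observations; use :func:`run_mc_study` to
    count invalid draws.
    """
    params = _as_param_table(cohort_fits, design.generator)
    delays = np.asarray(design.delays, dtype=float)
    rng = np.random.default_rng(design.seed)
    series = []
    for sid, k, scale in params:
        if design.generator == "normal":
            y = np.clip(simulate_normal_subject(k, scale, delays, rng), 0.0, 1.0)
        else:
            y = simulate_beta_subject(k, scale, delays, rng)
        series.append(IndifferencePointSeries(subject_id=sid, delays=delays, values=y))
    return Cohort(series)


def _sample_boundary_series(mu: np.ndarray, phi: float, eps_boundary: float, rng) -> np.ndarray:
    """Series for a boundary-exhibiting subject.

    z is drawn from the *untruncated* beta and mapped through the inverse
    SLT transform; draws landing outside the truncation interval snap to
    the exact endpoints (z <= l -> 0, z >= 1/s + l -> 1).  If no draw
    lands outside, the delay whose mean is most extreme is set to its
    nearest boundary so the subject honors its boundary flag.
    """
    s, l = eps_to_scale_location(eps_boundary)
    z = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(s * (z - l), 0.0, 1.0)
    if not np.any((y == 0.0) | (y == 1.0)):
        j = int(np.argmax(np.abs(mu - 0.5)))
        y[j] = 0.0 if mu[j] < 0.5 else 1.0
    return y


def generate_synthetic_cohort(
    n_subjects: int,
    delays: Sequence[float] = DEFAULT_DELAYS,
    lnk_mean: float = -4.9,
    lnk_sd: float = 1.8,
    phi_law: tuple[float, float] = (np.log(20.0), 0.5),
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
    eps: float = 1e-4,
    eps_boundary: float = 0.08,
    seed: int | None = None,
) -> Cohort:
    """Draw a synthetic cohort emulating real monetary-choice data.

    Per subject: psi ~ Normal(lnk_mean, lnk_sd^2), ln(phi) ~
    Normal(*phi_law), and a Bernoulli(boundary_fraction) flag.  Unflagged
    subjects are sampled from the truncated SLT law (half-margin ``eps``),
    which keeps values in [0, 1] with exact endpoints essentially absent;
    flagged subjects are sampled with the wider ``eps_boundary`` margin
    and endpoint snapping so each exhibits at least one exact 0 or 1.
    Fully reproducible given ``seed``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    delays = np.asarray(delays, dtype=float)
    rng = np.random.default_rng(seed)
    width = len(str(n_subjects))
    series = []
    for i in range(n_subjects):
        psi = rng.normal(lnk_mean, lnk_sd)
        phi = float(np.exp(rng.normal(phi_law[0], phi_law[1])))
        boundary = rng.uniform() < boundary_fraction
        mu = 1.0 / (1.0 + np.exp(psi) * delays)
        if boundary:
            y = _sample_boundary_series(mu, phi, eps_boundary, rng)
        else:
            y = np.array(
                [
                    slt_sample(SltBetaParams.from_eps(m, phi, eps), 1, rng)[0]
                    for m in mu
                ]
            )
        series.append(
            IndifferencePointSeries(
                subject_id=f"S{i + 1:0{width}d}", delays=delays, values=y
            )
        )
    return Cohort(series)
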