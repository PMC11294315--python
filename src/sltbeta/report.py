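"""Human-readable reporting: ln(k) summary tables and diagnostic panels.

Plots are diagnostics, not analysis surfaces; all numbers a downstream
consumer should rely on come from the serialized tables.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import lnk_summary

_SUMMARY_COLS = ["min", "q1", "median", "q3", "max", "mean", "sd"]


def lnk_summary_table(fits_df: pd.DataFrame) -> pd.DataFrame:
    """Per-method min/Q1/median/Q3/max/mean/SD of ln(k_hat) estimates.

    Expects a fits frame with ``method`` and ``psi_hat`` columns (one row
    per subject x method), as written by the ``fit`` CLI subcommand.
    """
    for col in ("method", "psi_hat"):
        if col not in fits_df.columns:
            raise ValidationError(f"fits table lacks required column {col!r}")
    rows = {m: lnk_summary(g["psi_hat"]) for m, g in fits_df.groupby("method")}
    return pd.DataFrame(rows).T[_SUMMARY_COLS]


def _paired_lnk(fits_df: pd.DataFrame) -> pd.DataFrame:
    wide = fits_df.pivot(index="subject", columns="method", values="psi_hat")
    if wide.shape[1] < 2:
        raise ValidationError("need fits from two methods for a scatter")
    return wide


def plot_lnk_scatter(fits_df: pd.DataFrame, ax=None):
    """NLS-vs-SLT ln(k_hat) scatter with the line of equality."""
    wide = _paired_lnk(fits_df)
    xcol, ycol = wide.columns[:2]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(wide[xcol], wide[ycol], s=14, alpha=0.7)
    lims = [wide.min().min(), wide.max().max()]
    ax.plot(lims, lims, color="red", lw=1, label="y = x")
    ax.set_xlabel(f"ln(k) — {xcol}")
    ax.set_ylabel(f"ln(k) — {ycol}")
    ax.legend()
    return ax


def plot_variance_profiles(fits, ax=None):
    """Model-implied variance vs delay rank for a set of SubjectFit objects.

    Beta-method profiles are drawn per subject; NLS constant variances,
    when present, are overlaid as horizontal reference lines.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for f in fits:
        ranks = np.arange(1, f.n_points + 1)
        prof = f.per_delay_variance
        if f.method == "nls":
            ax.plot(ranks, prof, color="grey", lw=0.8, alpha=0.5)
        else:
            ax.plot(ranks, prof, color="C0", lw=0.8, alpha=0.5)
    ax.set_xlabel("delay rank")
    ax.set_ylabel("model variance")
    return ax


def plot_invalid_by_delay(summary, delays=None, ax=None):
    """Proportion of invalid simulated points at each delay."""
    props = np.asarray(summary.prop_invalid_by_delay, dtype=float)
    x = np.arange(1, props.size + 1) if delays is None else np.asarray(delays, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(np.arange(props.size), props, tick_label=[f"{v:g}" for v in x])
    ax.set_xlabel("delay")
    ax.set_ylabel("proportion invalid")
    return ax


def render_report(fits_df: pd.DataFrame, screening_df: pd.DataFrame | None = None,
                  mc_summaries: dict | None = None) -> str:
    """Assemble the plain-text report body."""
    parts = ["ln(k) summary by method", lnk_summary_table(fits_df).to_string(
        float_format=lambda v: f"{v: .3f}")]
    try:
        wide = _paired_lnk(fits_df)
        a, b = wide.columns[:2]
        if np.allclose(wide[a], wide[b]):
            r = 1.0
        else:
            r = float(np.corrcoef(wide[a], wide[b])[0, 1])
        parts.append(f"\nPearson r of paired ln(k) ({a} vs {b}): {r:.4f}")
    except ValidationError:
        pass
    if screening_df is not None and len(screening_df):
        n = len(screening_df)
        n_pass = int(screening_df["passes"].sum())
        parts.append(f"\nScreening: {n_pass}/{n} subjects pass the Johnson–Bickel criteria")
    if mc_summaries:
        parts.append("\nMonte Carlo invalid-point study")
        for name, summ in mc_summaries.items():
            d = summ.to_dict() if hasattr(summ, "to_dict") else summ
            parts.append(
                f"  {name}: prop invalid points = {d['prop_invalid_points']:.4f}, "
                f"prop subjects with any invalid = {d['prop_subjects_any_invalid']:.4f}"
            )
    return "\n".join(parts)
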