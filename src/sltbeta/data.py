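"""Domain types and tabular I/O for indifference-point data.

An *indifference point* at delay ``D`` is the proportion of a larger-later
reward ``A`` at which a subject is indifferent between the immediate and
delayed options.  Raw currency amounts are normalized to the unit interval
by dividing by ``A``; values of exactly 0 and 1 are legal observations (a
subject may fully discount a long delay, or not discount a short one at
all), and downstream models must accommodate them.

The canonical file layout is a tidy long-format CSV with one row per
(subject, delay): ``subject,delay,value[,amount]``.  A wide layout (one
column per delay) is supported behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

DEFAULT_SCHEMA: Mapping[str, str] = {
    "subject": "subject",
    "delay": "delay",
    "value": "value",
    "amount": "amount",
}


def normalize_series(raw_values: Sequence[float], larger_later_amount: float) -> np.ndarray:
    """Rescale raw indifference amounts to proportions of the larger-later amount.

    Parameters
    ----------
    raw_values : sequence of float
        Indifference amounts in currency units, each in ``[0, A]``.
    larger_later_amount : float
        The larger-later amount ``A`` (> 0).

    Returns
    -------
    numpy.ndarray
        ``raw_values / A`` elementwise; every entry lies in ``[0, 1]``.

    Raises
    ------
    ValidationError
        If ``A <= 0`` or any raw value falls outside ``[0, A]`` (the
        message names the offending index).
    """
    A = float(larger_later_amount)
    if not np.isfinite(A) or A <= 0:
        raise ValidationError(f"larger_later_amount must be positive, got {larger_later_amount!r}")
    raw = np.asarray(raw_values, dtype=float)
    bad = np.nonzero((raw < 0) | (raw > A) | ~np.isfinite(raw))[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"raw value {raw[i]!r} at index {i} is outside [0, {A}]"
        )
    return raw / A


@dataclass(frozen=True)
class IndifferencePointSeries:
    """One subject's delays and normalized indifference points.

    Attributes
    ----------
    subject_id : str
        Opaque subject label.
    delays : numpy.ndarray
        Strictly increasing positive delays, in the user's time units
        (units are carried opaquely; the discounting rate ``k`` is
        reported in reciprocal units of these delays).
    values : numpy.ndarray
        Normalized indifference points in ``[0, 1]``, one per delay.
        Endpoint values 0 and 1 are legal.
    larger_later_amount : float or None
        The amount ``A`` the values were normalized by, if known.
    """

    subject_id: str
    delays: np.ndarray
    values: np.ndarray
    larger_later_amount: float | None = None

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "values", values)
        if delays.ndim != 1 or values.ndim != 1 or delays.size != values.size:
            raise ValidationError(
                f"subject {self.subject_id!r}: delays and values must be 1-d and equal length"
            )
        if delays.size < 2:
            raise ValidationError(
                f"subject {self.subject_id!r}: need at least 2 indifference points, got {delays.size}"
            )
        if not np.all(np.isfinite(delays)) or np.any(delays <= 0):
            raise ValidationError(f"subject {self.subject_id!r}: delays must be positive and finite")
        if np.any(np.diff(delays) <= 0):
            raise ValidationError(f"subject {self.subject_id!r}: delays must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any((values < 0) | (values > 1)):
            bad = np.nonzero(~np.isfinite(values) | (values < 0) | (values > 1))[0][0]
            raise ValidationError(
                f"subject {self.subject_id!r}: value {values[bad]!r} at delay "
                f"{delays[bad]!r} is outside [0, 1]"
            )
        if self.larger_later_amount is not None and self.larger_later_amount <= 0:
            raise ValidationError(f"subject {self.subject_id!r}: larger_later_amount must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.delays.size)

    def has_boundary(self, tol: float = 0.0) -> bool:
        """True if any point equals 0 or 1 (exactly, or within ``tol``)."""
        return bool(np.any(self.values <= tol) or np.any(self.values >= 1.0 - tol))


@dataclass
class Cohort:
    """A collection of subjects sharing (by default) a common delay grid."""

    series: list[IndifferencePointSeries] = field(default_factory=list)
    require_common_grid: bool = True

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.series]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids in cohort: {dup}")
        if self.require_common_grid and len(self.series) > 1:
            grid = self.series[0].delays
            for s in self.series[1:]:
                if s.delays.size != grid.size or not np.allclose(s.delays, grid):
                    raise ValidationError(
                        f"subject {s.subject_id!r} has a different delay grid; "
                        "pass require_common_grid=False to allow ragged cohorts"
                    )

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[IndifferencePointSeries]:
        return iter(self.series)

    def __getitem__(self, i: int) -> IndifferencePointSeries:
        return self.series[i]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.series]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame with columns subject, delay, value[, amount]."""
        rows = []
        for s in self.series:
            for d, v in zip(s.delays, s.values):
                row = {"subject": s.subject_id, "delay": d, "value": v}
                if s.larger_later_amount is not None:
                    row["amount"] = s.larger_later_amount
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _coerce_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.index[out.isna() & df[col].notna()]
    if len(bad):
        # +2: header row plus 1-based numbering, matching what an editor shows
        raise ValidationError(
            f"non-numeric {col} {df[col].loc[bad[0]]!r} at file row {int(bad[0]) + 2}"
        )
    return out


def cohort_from_dataframe(
    df: pd.DataFrame,
    schema: Mapping[str, str] | None = None,
    require_common_grid: bool = True,
) -> Cohort:
    """Build a :class:`Cohort` from a tidy long-format frame.

    Values are normalized by the amount column when one is present;
    otherwise they must already lie in [0, 1].
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    for key in ("subject", "delay", "value"):
        if sch[key] not in df.columns:
            raise SchemaError(f"missing required column {sch[key]!r}")
    has_amount = sch["amount"] in df.columns

    work = pd.DataFrame(
        {
            "subject": df[sch["subject"]].astype(str),
            "delay": _coerce_numeric(df, sch["delay"]),
            "value": _coerce_numeric(df, sch["value"]),
        }
    )
    if has_amount:
        work["amount"] = _coerce_numeric(df, sch["amount"])

    dup = work.duplicated(subset=["subject", "delay"], keep=False)
    if dup.any():
        pairs = work.loc[dup, ["subject", "delay"]].drop_duplicates()
        raise ValidationError(
            "duplicate (subject, delay) rows: "
            + ", ".join(f"({r.subject}, {r.delay:g})" for r in pairs.itertuples())
        )

    series = []
    for sid, grp in work.groupby("subject", sort=True):
        grp = grp.sort_values("delay")
        amount = None
        values = grp["value"].to_numpy()
        if has_amount:
            amounts = grp["amount"].unique()
            if len(amounts) != 1:
                raise ValidationError(f"subject {sid!r}: multiple larger-later amounts {amounts}")
            amount = float(amounts[0])
            values = normalize_series(values, amount)
        series.append(
            IndifferencePointSeries(
                subject_id=str(sid),
                delays=grp["delay"].to_numpy(),
                values=values,
                larger_later_amount=amount,
            )
        )
    return Cohort(series, require_common_grid=require_common_grid)


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    require_common_grid: bool = True,
    wide: bool = False,
) -> Cohort:
    """Read a cohort from a tidy CSV (or, with ``wide=True``, one column per delay).

    In the wide layout the first column is the subject id and each remaining
    column name is parsed as a delay.
    """
    df = pd.read_csv(path)
    if wide:
        df = df.melt(id_vars=[df.columns[0]], var_name="delay", value_name="value")
        df = df.rename(columns={df.columns[0]: "subject"})
        schema = None
    return cohort_from_dataframe(df, schema=schema, require_common_grid=require_common_grid)


def count_boundary_subjects(cohort: Cohort, tol: float = 0.0) -> int:
    """Number of subjects with at least one indifference point exactly 0 or 1.

    ``tol`` widens the detection window for files that store e.g. 0.9999999;
    the default 0 treats the endpoints as exact observable outcomes.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    return sum(1 for s in cohort if s.has_boundary(tol))
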