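"""Johnson–Bickel screening for systematic delay discounters.

Two rules, applied to a subject's normalized indifference points ordered
by delay:

C1  no indifference point rises above its predecessor by more than 20%
    of the larger-later amount (no consecutive increase > 0.2), and
C2  the last indifference point is at least 10% of the larger-later
    amount below the first (first - last >= 0.1).

A subject passes when neither rule is violated.  Both thresholds are
parameters with those defaults; violation uses strict inequality by
default (a rise of exactly 0.2 does not violate C1), configurable to
weak inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort, IndifferencePointSeries


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the Johnson–Bickel screen for one subject.

    c1_max_rise is the largest increase between consecutive indifference
    points (0 if the series never rises); c2_drop is first minus last.
    ``passes`` is True iff ``violated_criteria`` is empty.
    """

    subject_id: str
    passes: bool
    violated_criteria: frozenset[str]
    c1_max_rise: float
    c2_drop: float

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "passes": self.passes,
            "violates_c1": "C1" in self.violated_criteria,
            "violates_c2": "C2" in self.violated_criteria,
            "c1_max_rise": self.c1_max_rise,
            "c2_drop": self.c2_drop,
        }


def johnson_bickel(
    series: IndifferencePointSeries,
    c1_threshold: float = 0.2,
    c2_threshold: float = 0.1,
    strict: bool = True,
) -> ScreeningResult:
    """Apply the two-rule screen to one subject.

    With ``strict=True`` (default) C1 is violated when a consecutive rise
    strictly exceeds ``c1_threshold``; with ``strict=False`` a rise equal
    to the threshold also violates.  C2 is violated when the first-to-last
    drop falls short of ``c2_threshold``.
    """
    y = series.values
    rises = np.diff(y)
    max_rise = float(max(np.max(rises), 0.0)) if rises.size else 0.0
    drop = float(y[0] - y[-1])
    violated = set()
    if (max_rise > c1_threshold) or (not strict and max_rise >= c1_threshold):
        violated.add("C1")
    if (drop < c2_threshold) or (not strict and drop <= c2_threshold):
        violated.add("C2")
    return ScreeningResult(
        subject_id=series.subject_id,
        passes=not violated,
        violated_criteria=frozenset(violated),
        c1_max_rise=max_rise,
        c2_drop=drop,
    )


def screen_cohort(
    cohort: Cohort,
    c1_threshold: float = 0.2,
    c2_threshold: float = 0.1,
    strict: bool = True,
) -> tuple[Cohort, pd.DataFrame]:
    """Partition a cohort into passers and report per-subject results.

    Returns the passing sub-cohort and a table with one row per subject
    (pass flag, violated criteria, and both screening statistics);
    passes + failures always account for every input subject.
    """
    results = [
        johnson_bickel(s, c1_threshold, c2_threshold, strict=strict) for s in cohort
    ]
    passing = Cohort(
        [s for s, r in zip(cohort, results) if r.passes],
        require_common_grid=cohort.require_common_grid,
    )
    table = pd.DataFrame([r.to_dict() for r in results]) if results else pd.DataFrame(
        columns=["subject", "passes", "violates_c1", "violates_c2", "c1_max_rise", "c2_drop"]
    )
    return passing, table
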