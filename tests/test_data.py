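import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sltbeta import (
    Cohort,
    IndifferencePointSeries,
    SchemaError,
    ValidationError,
    cohort_from_dataframe,
    count_boundary_subjects,
    normalize_series,
    read_cohort,
)


class TestNormalizeSeries:
    @pytest.mark.parametrize(
        "raw, amount, expected",
        [
            ([87], 100, [0.87]),
            ([0, 100], 100, [0.0, 1.0]),
            ([25, 50, 75], 100, [0.25, 0.50, 0.75]),
        ],
    )
    def test_division_by_larger_later_amount(self, raw, amount, expected):
        np.testing.assert_array_equal(normalize_series(raw, amount), expected)

    def test_rejects_nonpositive_amount(self):
        with pytest.raises(ValidationError):
            normalize_series([1.0], 0.0)

    def test_rejects_out_of_range_value_naming_index(self):
        with pytest.raises(ValidationError, match="index 1"):
            normalize_series([50, 120], 100)
        with pytest.raises(ValidationError, match="index 0"):
            normalize_series([-3, 50], 100)

    @given(
        raw=st.lists(st.integers(min_value=0, max_value=128), min_size=1, max_size=10),
        exponent=st.integers(min_value=0, max_value=7),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_power_of_two_amounts_round_trip_exactly(self, raw, exponent):
        A = float(2**exponent) * 128.0  # power-of-two amount: division is exact
        raw = [min(r, A) for r in raw]
        back = normalize_series(raw, A) * A
        np.testing.assert_array_equal(back, np.asarray(raw, dtype=float))


class TestIndifferencePointSeries:
    def test_requires_two_points(self):
        with pytest.raises(ValidationError):
            IndifferencePointSeries("a", [1.0], [0.5])

    def test_requires_strictly_increasing_delays(self):
        with pytest.raises(ValidationError, match="increasing"):
            IndifferencePointSeries("a", [1.0, 1.0], [0.5, 0.4])

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            IndifferencePointSeries("a", [1.0, 2.0], [0.5, 1.2])

    def test_endpoint_values_are_legal(self):
        s = IndifferencePointSeries("a", [1.0, 2.0], [1.0, 0.0])
        assert s.has_boundary()

    def test_boundary_tolerance_widens_detection(self):
        s = IndifferencePointSeries("a", [1.0, 2.0], [0.9999999, 0.3])
        assert not s.has_boundary()
        assert s.has_boundary(tol=1e-6)


class TestCohortIO:
    def _csv(self, text):
        return io.StringIO(text)

    def test_round_trip_preserves_ids_delays_values(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        small_cohort.write_csv(path)
        back = read_cohort(path)
        assert back.subject_ids == small_cohort.subject_ids
        for a, b in zip(small_cohort, back):
            np.testing.assert_allclose(a.delays, b.delays)
            np.testing.assert_allclose(a.values, b.values)

    def test_out_of_order_delays_are_sorted(self):
        df = pd.DataFrame(
            {"subject": ["a"] * 3, "delay": [30, 7, 90], "value": [0.5, 0.9, 0.2]}
        )
        cohort = cohort_from_dataframe(df)
        np.testing.assert_array_equal(cohort[0].delays, [7, 30, 90])
        np.testing.assert_array_equal(cohort[0].values, [0.9, 0.5, 0.2])

    def test_value_above_one_without_amount_is_rejected(self):
        df = pd.DataFrame({"subject": ["a", "a"], "delay": [7, 30], "value": [0.5, 1.2]})
        with pytest.raises(ValidationError):
            cohort_from_dataframe(df)

    def test_amount_column_triggers_normalization(self):
        df = pd.DataFrame(
            {
                "subject": ["a", "a"],
                "delay": [7, 30],
                "value": [87.0, 25.0],
                "amount": [100.0, 100.0],
            }
        )
        cohort = cohort_from_dataframe(df)
        np.testing.assert_array_equal(cohort[0].values, [0.87, 0.25])
        assert cohort[0].larger_later_amount == 100.0

    def test_missing_column_names_it(self):
        df = pd.DataFrame({"subject": ["a", "a"], "delay": [7, 30]})
        with pytest.raises(SchemaError, match="value"):
            cohort_from_dataframe(df)

    def test_non_numeric_value_reports_row(self):
        cohort_csv = "subject,delay,value\na,7,0.5\na,30,oops\n"
        with pytest.raises(ValidationError, match="row 3"):
            read_cohort(self._csv(cohort_csv))

    def test_duplicate_subject_delay_rows_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a", "a"], "delay": [7, 7], "value": [0.5, 0.6]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            cohort_from_dataframe(df)

    def test_schema_mapping_renames_columns(self):
        df = pd.DataFrame({"id": ["a", "a"], "days": [7, 30], "ip": [0.9, 0.4]})
        cohort = cohort_from_dataframe(
            df, schema={"subject": "id", "delay": "days", "value": "ip"}
        )
        assert cohort.subject_ids == ["a"]

    def test_wide_format_reader(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text("subject,7,30,90\na,0.9,0.5,0.2\nb,0.8,0.6,0.1\n")
        cohort = read_cohort(path, wide=True)
        assert len(cohort) == 2
        np.testing.assert_array_equal(cohort[0].delays, [7, 30, 90])

    def test_common_grid_enforced_unless_relaxed(self):
        df = pd.DataFrame(
            {"subject": ["a", "a", "b", "b"], "delay": [7, 30, 7, 60],
             "value": [0.9, 0.5, 0.8, 0.3]}
        )
        with pytest.raises(ValidationError, match="grid"):
            cohort_from_dataframe(df)
        cohort = cohort_from_dataframe(df, require_common_grid=False)
        assert len(cohort) == 2


class TestCountBoundarySubjects:
    def test_counts_series_with_any_endpoint(self, delays):
        mk = lambda sid, v: IndifferencePointSeries(sid, delays[:3], np.asarray(v))
        cohort = Cohort(
            [
                mk("a", [0.9, 0.5, 0.2]),
                mk("b", [1.0, 0.5, 0.2]),
                mk("c", [0.8, 0.4, 0.1]),
            ]
        )
        assert count_boundary_subjects(cohort) == 1

    def test_zero_when_no_boundary_values(self, delays):
        cohort = Cohort(
            [IndifferencePointSeries("a", delays[:2], np.array([0.9, 0.4]))]
        )
        assert count_boundary_subjects(cohort) == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            count_boundary_subjects(Cohort([]))

    def test_duplicate_ids_rejected(self, delays):
        s = IndifferencePointSeries("a", delays[:2], np.array([0.9, 0.4]))
        with pytest.raises(ValidationError, match="duplicate"):
            Cohort([s, s])
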