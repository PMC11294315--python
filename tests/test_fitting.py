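import numpy as np
import pytest

from sltbeta import (
    IndifferencePointSeries,
    NLSDiscounting,
    SLTBetaRegression,
    ValidationError,
    compare_lnk,
    fit_nls,
    fit_slt_beta,
    fit_vanilla_beta,
    fit_cohort,
    fits_to_dataframe,
    lnk_summary,
    variance_profile,
)
from sltbeta.distribution import slt_loglik


class TestNLS:
    def test_noiseless_recovery(self, noiseless_series):
        fit = fit_nls(noiseless_series)
        assert fit.k_hat == pytest.approx(0.05, abs=1e-6)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_sigma2_uses_d_minus_one_divisor(self, delays):
        rng = np.random.default_rng(5)
        y = np.clip(1.0 / (1.0 + 0.01 * delays) + rng.normal(0, 0.05, delays.size), 0, 1)
        fit = fit_nls(IndifferencePointSeries("s", delays, y))
        resid = y - fit.fitted_means
        assert fit.sigma2_hat == pytest.approx(np.sum(resid**2) / (delays.size - 1))

    def test_matches_brute_force_grid(self, delays):
        # independent oracle: dense scan of the SSE objective
        rng = np.random.default_rng(9)
        y = np.clip(1.0 / (1.0 + 0.008 * delays) + rng.normal(0, 0.08, delays.size), 0, 1)
        series = IndifferencePointSeries("s", delays, y)
        fit = fit_nls(series)
        model = NLSDiscounting(series)
        grid = np.linspace(-15.0, 5.0, 100_000)
        best_sse = min(model._sse(p) for p in grid)
        assert fit.sse <= best_sse + 1e-8

    def test_no_discounting_flagged_not_silent(self, delays):
        fit = fit_nls(IndifferencePointSeries("flat", delays, np.ones(delays.size)))
        assert fit.at_boundary
        assert not fit.converged
        assert fit.message

    def test_from_dataframe_constructor(self, delays):
        import pandas as pd

        df = pd.DataFrame(
            {"subject": "a", "delay": delays, "value": 1.0 / (1.0 + 0.05 * delays)}
        )
        fit = NLSDiscounting.from_dataframe(df).fit()
        assert fit.k_hat == pytest.approx(0.05, abs=1e-6)


class TestSLTBeta:
    def test_endpoint_data_fits_finitely(self, boundary_series):
        fit = fit_slt_beta(boundary_series)
        assert np.isfinite(fit.log_likelihood)
        assert fit.converged

    def test_optimum_beats_surrounding_grid(self, delays):
        rng = np.random.default_rng(2)
        mu = 1.0 / (1.0 + np.exp(-4.9) * delays)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        series = IndifferencePointSeries("s", delays, y)
        fit = fit_slt_beta(series)
        psis = fit.psi_hat + np.linspace(-0.5, 0.5, 200)
        taus = np.log(fit.phi_hat) + np.linspace(-0.5, 0.5, 200)
        grid_best = -np.inf
        for tau in taus:
            phi = np.exp(tau)
            for psi in psis:
                ll = slt_loglik(y, 1.0 / (1.0 + np.exp(psi) * delays), phi, 1e-4)
                grid_best = max(grid_best, ll)
        assert fit.log_likelihood >= grid_best - 1e-6

    def test_mean_recovery_over_replicates(self, delays):
        # light-weight recovery check (the full 3x3 design runs in the
        # acceptance suite): 40 replicate subjects at psi*=-4.9, phi*=20
        rng = np.random.default_rng(21)
        psi_true, phi_true = -4.9, 20.0
        mu = 1.0 / (1.0 + np.exp(psi_true) * delays)
        hats = []
        for i in range(40):
            y = rng.beta(mu * phi_true, (1 - mu) * phi_true)
            hats.append(fit_slt_beta(IndifferencePointSeries(str(i), delays, y)).psi_hat)
        hats = np.asarray(hats)
        assert abs(hats.mean() - psi_true) < 0.1

    def test_series_with_out_of_bounds_value_rejected(self, delays):
        with pytest.raises(ValidationError):
            SLTBetaRegression(
                IndifferencePointSeries("b", delays, np.linspace(1.2, 0, delays.size))
            )


class TestVanillaBeta:
    def test_boundary_value_raises_documented_limitation(self, boundary_series):
        with pytest.raises(ValidationError, match="0 or 1"):
            fit_vanilla_beta(boundary_series)

    def test_noiseless_interior_recovery(self, delays):
        mu = 1.0 / (1.0 + np.exp(-4.9) * delays)
        fit = fit_vanilla_beta(IndifferencePointSeries("c", delays, mu))
        assert fit.psi_hat == pytest.approx(-4.9, abs=1e-4)

    def test_agrees_with_slt_at_tiny_margin(self, delays):
        rng = np.random.default_rng(14)
        mu = 1.0 / (1.0 + np.exp(-4.9) * delays)
        y = rng.beta(mu * 15, (1 - mu) * 15)
        series = IndifferencePointSeries("s", delays, y)
        a = fit_vanilla_beta(series).psi_hat
        b = fit_slt_beta(series, eps=1e-6).psi_hat
        assert a == pytest.approx(b, abs=1e-3)


class TestVarianceProfile:
    def test_nls_profile_is_constant(self, delays):
        rng = np.random.default_rng(4)
        y = np.clip(1.0 / (1.0 + 0.01 * delays) + rng.normal(0, 0.05, delays.size), 0, 1)
        fit = fit_nls(IndifferencePointSeries("s", delays, y))
        prof = variance_profile(fit)
        assert prof.shape == (delays.size,)
        np.testing.assert_allclose(prof, fit.sigma2_hat)

    def test_beta_profile_matches_variance_function(self, delays):
        rng = np.random.default_rng(6)
        mu = 1.0 / (1.0 + np.exp(-4.9) * delays)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        fit = fit_slt_beta(IndifferencePointSeries("s", delays, y))
        expected = fit.fitted_means * (1 - fit.fitted_means) / (1 + fit.phi_hat)
        np.testing.assert_allclose(variance_profile(fit), expected)

    def test_profile_peaks_where_mean_crosses_half(self, delays):
        rng = np.random.default_rng(8)
        mu = 1.0 / (1.0 + np.exp(-4.9) * delays)  # spans ~0.9 .. ~0.1
        y = rng.beta(mu * 20, (1 - mu) * 20)
        fit = fit_slt_beta(IndifferencePointSeries("s", delays, y))
        prof = fit.per_delay_variance
        peak = np.argmax(prof)
        assert abs(fit.fitted_means[peak] - 0.5) == np.min(np.abs(fit.fitted_means - 0.5))
        assert prof[peak] > prof[0] and prof[peak] > prof[-1]


class TestComparison:
    def _fits(self, delays, n=6, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            mu = 1.0 / (1.0 + np.exp(rng.normal(-4.9, 1.0)) * delays)
            y = rng.beta(mu * 20, (1 - mu) * 20)
            out.append(fit_nls(IndifferencePointSeries(f"s{i}", delays, y)))
        return out

    def test_identical_fit_sets_agree_perfectly(self, delays):
        fits = self._fits(delays)
        cmp = compare_lnk(fits, fits)
        assert cmp.pearson_r == 1.0
        assert (cmp.summary.iloc[0] == cmp.summary.iloc[1]).all()

    def test_unmatched_subjects_are_listed(self, delays):
        fits = self._fits(delays)
        with pytest.raises(ValidationError, match="s5"):
            compare_lnk(fits, fits[:-1])

    def test_summary_statistics_match_hand_computation(self):
        # five-point vector where quartiles are hand-checkable under
        # linear interpolation: sorted [-8, -6, -5, -3, -1]
        values = [-5.0, -8.0, -1.0, -6.0, -3.0]
        s = lnk_summary(values)
        assert s["min"] == -8.0 and s["max"] == -1.0
        assert s["median"] == -5.0
        assert s["q1"] == -6.0 and s["q3"] == -3.0
        assert s["mean"] == pytest.approx(-4.6)
        assert s["sd"] == pytest.approx(np.std(values, ddof=1))


class TestCohortFitting:
    def test_both_methods_give_two_rows_per_subject(self, small_cohort):
        fits = fit_cohort(small_cohort, method="both")
        assert len(fits) == 2 * len(small_cohort)
        df = fits_to_dataframe(fits)
        assert set(df["method"]) == {"nls", "slt_beta"}
        assert df.groupby("subject").size().eq(2).all()

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            fit_cohort(small_cohort, method="wls")
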