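"""CCF lag identification, weight profiles, and weighted-exposure construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alcolag import (AnnualSeries, CcfResult, LagWeightProfile, SimulationConfig,
                     apply_weights, ccf_weights, cross_correlate,
                     geometric_weights, point_mass_weights, prewhiten,
                     select_lag_length, simulate_exposure, simulate_mortality,
                     uniform_weights)


def _series(values, start=1900, label="x"):
    return AnnualSeries(label=label, start_year=start,
                        values=np.asarray(values, float))


class TestCcfResult:
    def test_critical_band_at_n69(self):
        # the two-sided band is 2/sqrt(n); at n = 69 overlapping years this
        # is 0.2408, i.e. 0.240 at the precision a study report prints
        r = CcfResult(lags=np.arange(3), ccf=np.array([0.1, 0.3, -0.05]),
                      n_effective=69)
        assert r.critical_value == pytest.approx(2 / np.sqrt(69))
        assert r.critical_value == pytest.approx(0.2408, abs=5e-5)
        assert r.significant_lags == {1}

    def test_significance_uses_absolute_value(self):
        r = CcfResult(lags=np.arange(2), ccf=np.array([-0.9, 0.1]), n_effective=50)
        assert 0 in r.significant_lags


class TestCrossCorrelate:
    def test_pure_lag_construction_peaks_at_three(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        y = np.concatenate([rng.normal(size=3) * 0.01, x[:-3]])
        r = cross_correlate(x, y, 10)
        assert r[3] == pytest.approx(1.0, abs=0.05)
        assert int(np.argmax(r.ccf)) == 3

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            cross_correlate(np.ones(50), np.random.default_rng(0).normal(size=50), 5)

    def test_max_lag_bounded_by_half_length(self):
        z = np.random.default_rng(0).normal(size=40)
        with pytest.raises(ValueError, match="too large"):
            cross_correlate(z, z, 25)


class TestSelectLagLength:
    def _ccf(self, vals, n=69):
        return CcfResult(lags=np.arange(len(vals)), ccf=np.asarray(vals),
                         n_effective=n)

    def test_largest_significant_positive_lag(self):
        vals = np.zeros(26)
        vals[[1, 7, 20]] = 0.3
        assert select_lag_length(self._ccf(vals)) == 20

    def test_no_significant_lag_gives_zero(self):
        assert select_lag_length(self._ccf(np.full(26, 0.1))) == 0

    def test_negative_correlations_never_select(self):
        vals = np.zeros(26)
        vals[15] = -0.5
        assert select_lag_length(self._ccf(vals)) == 0


class TestWeightProfiles:
    def test_ccf_weights_equal_split(self):
        vals = np.zeros(6)
        vals[[2, 4]] = 0.3
        prof = ccf_weights(CcfResult(lags=np.arange(6), ccf=vals, n_effective=69), 5)
        np.testing.assert_allclose(prof.weights[[2, 4]], 0.5)
        assert prof.weights[[0, 1, 3, 5]].sum() == 0

    def test_single_significant_lag_gets_all_weight(self):
        vals = np.zeros(21)
        vals[20] = 0.31
        prof = ccf_weights(CcfResult(lags=np.arange(21), ccf=vals, n_effective=69), 20)
        assert prof.weights[20] == pytest.approx(1.0)

    def test_uniform_fallback_when_nothing_significant(self):
        vals = np.full(6, 0.05)
        prof = ccf_weights(CcfResult(lags=np.arange(6), ccf=vals, n_effective=69), 5)
        np.testing.assert_allclose(prof.weights, 1 / 6)

    def test_geometric_closed_form(self):
        prof = geometric_weights(1, 0.5)
        np.testing.assert_allclose(prof.weights, [2 / 3, 1 / 3])

    def test_geometric_monotone_and_normalised(self):
        prof = geometric_weights(20, 0.9)
        assert np.all(np.diff(prof.weights) < 0)
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_geometric_decay_near_one_approaches_uniform(self):
        prof = geometric_weights(5, 0.999999)
        np.testing.assert_allclose(prof.weights, 1 / 6, atol=1e-5)

    def test_geometric_rejects_bad_decay(self):
        for decay in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                geometric_weights(15, decay)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LagWeightProfile(scheme="uniform", weights=np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="non-negative"):
            LagWeightProfile(scheme="uniform", weights=np.array([1.5, -0.5]))

    @given(L=st.integers(min_value=0, max_value=30),
           decay=st.floats(min_value=0.05, max_value=0.99))
    @settings(max_examples=50, deadline=None)
    def test_any_geometric_profile_is_proper(self, L, decay):
        prof = geometric_weights(L, decay)
        assert prof.max_lag == L
        assert np.all(prof.weights >= 0)
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestApplyWeights:
    def test_lag_zero_point_mass_is_identity(self):
        x = _series(np.random.default_rng(2).uniform(1, 5, 30))
        out = apply_weights(x, point_mass_weights(0))
        assert out.start_year == x.start_year
        np.testing.assert_allclose(out.values, x.values)

    def test_constant_series_is_conserved(self):
        x = _series(np.full(40, 7.5))
        out = apply_weights(x, geometric_weights(10, 0.8))
        np.testing.assert_allclose(out.values, 7.5, atol=1e-12)
        assert out.start_year == x.start_year + 10

    def test_linear_series_uniform_window(self):
        # x_t = t, uniform weights over lags 0..2 → WA_t = t - 1
        x = _series(np.arange(1900, 1930, dtype=float))
        out = apply_weights(x, uniform_weights(2))
        np.testing.assert_allclose(out.values, out.years - 1.0)

    def test_point_mass_is_pure_shift(self):
        x = _series(np.arange(30.0))
        out = apply_weights(x, point_mass_weights(5))
        np.testing.assert_allclose(out.values, x.values[:-5])
        assert out.start_year == x.start_year + 5

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            apply_weights(_series(np.ones(5)), geometric_weights(10, 0.9))

    def test_mean_preserved_for_stationary_series(self):
        rng = np.random.default_rng(9)
        x = _series(10 + rng.normal(size=2000))
        out = apply_weights(x, geometric_weights(15, 0.9))
        assert out.values.mean() == pytest.approx(x.values.mean(), abs=0.05)


class TestPrewhiten:
    def test_white_noise_selects_order_zero_identity(self):
        rng = np.random.default_rng(0)
        x = _series(np.cumsum(rng.normal(size=100)), label="x")
        y = _series(np.cumsum(rng.normal(size=100)), label="y")
        xr, yr = prewhiten(x, y)
        # differences of random walks are white; the AR filter should be the
        # identity (order 0), so the residuals equal the differenced inputs
        np.testing.assert_allclose(xr, np.diff(x.values))
        np.testing.assert_allclose(yr, np.diff(y.values))

    def test_constant_exposure_is_degenerate(self):
        y = _series(np.cumsum(np.random.default_rng(0).normal(size=50)))
        with pytest.raises(ValueError, match="degenerate"):
            prewhiten(_series(np.ones(50)), y)

    def test_too_short_errors(self):
        z = _series(np.random.default_rng(1).normal(size=10))
        with pytest.raises(ValueError, match="30"):
            prewhiten(z, z)

    def test_ar_filter_whitens_autocorrelated_exposure(self):
        from alcolag import ljung_box_q10
        rng = np.random.default_rng(17)
        n = 200
        dx = np.zeros(n)
        e = rng.normal(size=n)
        for t in range(1, n):
            dx[t] = 0.8 * dx[t - 1] + e[t]
        x = _series(np.cumsum(dx), label="x")
        y = _series(np.cumsum(rng.normal(size=n)), label="y")
        xr, _ = prewhiten(x, y)
        _, p = ljung_box_q10(xr)
        assert p > 0.05


class TestLagRecovery:
    def test_point_mass_lag_recovered_from_generated_data(self):
        """A known 20-year delay must dominate the pre-whitened CCF."""
        cfg = SimulationConfig(seed=42, n_years=150, exposure_shape="random-walk",
                               lag_profile_true=point_mass_weights(20),
                               noise_sd=0.002, ma1_theta=0.0)
        x = simulate_exposure(cfg)
        m = simulate_mortality(x, [], cfg)
        xr, yr = prewhiten(x, m)
        ccf = cross_correlate(xr, yr, 25)
        assert int(np.argmax(ccf.ccf)) == 20
        assert select_lag_length(ccf) <= ccf.max_lag
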