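"""Ground-truth generator: shapes, determinism, and the closed-form limit."""

import numpy as np
import pytest

from alcolag import (SimulationConfig, generate_study, point_mass_weights,
                     simulate_exposure, simulate_mortality)
from alcolag.synthetic_data import write_study


class TestSimulateExposure:
    def test_flat_shape_is_constant(self):
        cfg = SimulationConfig(seed=0, exposure_shape="flat", flat_level=10.0)
        x = simulate_exposure(cfg)
        np.testing.assert_allclose(x.values, 10.0)

    def test_same_seed_reproduces_exactly(self):
        a = simulate_exposure(SimulationConfig(seed=11))
        b = simulate_exposure(SimulationConfig(seed=11))
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = simulate_exposure(SimulationConfig(seed=11))
        b = simulate_exposure(SimulationConfig(seed=12))
        assert not np.array_equal(a.values, b.values)

    def test_paper_like_peak_in_middle_third(self):
        # mid-century rise, 1970s peak, later decline
        for seed in range(10):
            x = simulate_exposure(SimulationConfig(seed=seed))
            peak = int(np.argmax(x.values))
            assert len(x) / 3 < peak < 2 * len(x) / 3

    def test_nonnegative_everywhere(self):
        for shape in ("paper-like", "random-walk", "flat"):
            cfg = SimulationConfig(seed=5, exposure_shape=shape)
            assert np.all(simulate_exposure(cfg).values >= 0)

    def test_unknown_shape_rejected(self):
        cfg = SimulationConfig(seed=0)
        object.__setattr__(cfg, "exposure_shape", "banana")
        with pytest.raises(ValueError, match="banana"):
            simulate_exposure(cfg)


class TestSimulateMortality:
    def test_null_model_is_constant_at_baseline(self):
        cfg = SimulationConfig(seed=0, beta_true=0.0, noise_sd=1e-12,
                               ma1_theta=0.0, baseline_log_mortality=np.log(20.0))
        x = simulate_exposure(cfg)
        m = simulate_mortality(x, [], cfg)
        np.testing.assert_allclose(m.values, 20.0, rtol=1e-6)

    def test_flat_exposure_has_no_effect(self):
        # differencing kills constants: a flat exposure cannot move mortality
        cfg = SimulationConfig(seed=3, exposure_shape="flat", beta_true=0.5,
                               noise_sd=1e-12, ma1_theta=0.0)
        m = simulate_mortality(simulate_exposure(cfg), [], cfg)
        np.testing.assert_allclose(m.values, m.values[0], rtol=1e-6)

    def test_output_starts_lag_years_late(self):
        cfg = SimulationConfig(seed=1)
        x = simulate_exposure(cfg)
        m = simulate_mortality(x, [], cfg)
        assert m.start_year == x.start_year + cfg.lag_profile_true.max_lag
        assert m.end_year == x.end_year

    def test_mortality_strictly_positive(self):
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, noise_sd=0.05)
            m = simulate_mortality(simulate_exposure(cfg), [], cfg)
            assert np.all(m.values > 0)

    def test_noiseless_limit_recovers_beta_by_regression(self):
        """With no disturbance, OLS of Δlog M on ΔWA returns beta exactly."""
        from alcolag import apply_weights, difference, log_series
        cfg = SimulationConfig(seed=2, noise_sd=1e-14, ma1_theta=0.0,
                               beta_true=0.035)
        x = simulate_exposure(cfg)
        m = simulate_mortality(x, [], cfg)
        wa = apply_weights(x, cfg.lag_profile_true)
        dy = difference(log_series(m)).values
        dx = difference(wa).values
        beta = np.polyfit(dx, dy, 1)[0]
        assert beta == pytest.approx(0.035, abs=1e-7)

    def test_too_short_exposure_errors(self):
        cfg = SimulationConfig(seed=0)
        short = simulate_exposure(cfg).window(1910, 1930)
        with pytest.raises(ValueError, match="shorter"):
            simulate_mortality(short, [], cfg)


class TestGenerateStudy:
    def test_study_structure(self, default_study):
        ds, truth = default_study
        labels = {(s.label, s.sex.value) for s in ds.series}
        assert ("alcohol", "all") in labels
        assert ("tobacco", "all") in labels
        assert ("health_expenditure", "all") in labels
        assert ("total_cancer", "male") in labels and ("uadt", "female") in labels
        assert ("lung", "male") in labels
        assert truth["beta_true"]["lung__male"] == 0.0
        assert truth["beta_true"]["uadt__male"] == pytest.approx(0.035)

    def test_health_expenditure_recorded_later(self, default_study):
        ds, _ = default_study
        assert ds.get("health_expenditure").start_year == \
            ds.get("alcohol").start_year + 25

    def test_sidecar_round_trip(self, tmp_path, default_study):
        import json
        ds, truth = default_study
        write_study(ds, truth, tmp_path / "s.csv")
        sidecar = json.loads((tmp_path / "s.truth.json").read_text())
        assert sidecar["beta_true"] == {k: v for k, v in truth["beta_true"].items()}
        assert sidecar["lag_profile_true"] == truth["lag_profile_true"]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SimulationConfig(noise_sd=0.0)
        with pytest.raises(ValueError, match="lag length"):
            SimulationConfig(n_years=40, lag_profile_true=point_mass_weights(20))
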