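"""VPD formulas, the mass-loss inverse chain, plateau detection, g_min."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuticula import conductance as cond
from cuticula import synthetic as syn


class TestSaturationVapourPressure:
    def test_magnus_at_zero(self):
        assert cond.saturation_vapour_pressure(0.0) == pytest.approx(0.61094)

    def test_magnus_at_25(self):
        # direct independent evaluation of the Magnus expression
        expected = 0.61094 * np.exp(17.625 * 25.0 / (25.0 + 243.04))
        assert cond.saturation_vapour_pressure(25.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_temperature(self):
        assert cond.saturation_vapour_pressure(38.0) > cond.saturation_vapour_pressure(25.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cond.saturation_vapour_pressure(75.0)


class TestVpdMoleFraction:
    def test_saturated_air_gives_zero(self):
        assert cond.vpd_mole_fraction(20.0, 20.0, 100.0, 101.3) == 0.0

    def test_hand_evaluated_expression(self):
        es25 = 0.61094 * np.exp(17.625 * 25.0 / 268.04)
        expected = (es25 - 0.5 * es25) / 101.3
        assert cond.vpd_mole_fraction(25.0, 25.0, 50.0, 101.3) == pytest.approx(
            expected, rel=1e-12
        )

    def test_inverse_proportional_to_pressure(self):
        v1 = cond.vpd_mole_fraction(25.0, 25.0, 40.0, 100.0)
        v2 = cond.vpd_mole_fraction(25.0, 25.0, 40.0, 50.0 + 1e-9)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-6)

    @given(
        t=st.floats(0, 45),
        rh=st.floats(1, 99),
        p=st.floats(60, 110),
    )
    def test_non_negative(self, t, rh, p):
        assert cond.vpd_mole_fraction(t, t, rh, p) >= 0.0


def _toy_experiment(masses, interval_minutes=60, area=1e-3, temp=25.0, rh=50.0, p=101.3):
    ts = pd.date_range("2023-07-01", periods=len(masses), freq=f"{interval_minutes}min")
    return cond.DryingExperiment(
        sample_id="toy",
        timestamps=ts,
        masses=np.asarray(masses, dtype=float),
        ambient_temp=temp,
        relative_humidity=rh,
        pressure=p,
        projected_leaf_area=area,
    )


class TestConductanceSeries:
    def test_forward_inverse_identity_noiseless(self):
        """With no stomatal term, no noise and no desiccation, the inverse
        chain returns the true g_min at machine precision everywhere."""
        p = syn.DryingForwardParams(
            true_gmin=2.0, stomatal_g0=0.0, balance_noise_sd=0.0, duration=12.0
        )
        series = cond.conductance_series(syn.generate_drying_experiment(p))
        np.testing.assert_allclose(series.g, 2.0, rtol=1e-11)

    def test_inverse_matches_forward_g_with_stomatal_phase(self):
        p = syn.DryingForwardParams(
            true_gmin=1.5, stomatal_g0=6.0, balance_noise_sd=0.0, duration=12.0
        )
        exp = syn.generate_drying_experiment(p)
        series = cond.conductance_series(exp)
        np.testing.assert_allclose(series.g, exp.metadata["true_g_intervals"], rtol=1e-9)

    def test_zero_mass_change_gives_zero_g(self):
        exp = _toy_experiment([1.0, 0.99, 0.99, 0.98])
        series = cond.conductance_series(exp)
        assert series.g[1] == 0.0

    def test_toy_record_matches_hand_computation(self):
        # 3 intervals of 1 h, each losing 1 mg; A = 1e-3 m2, 25 degC, 50% RH
        exp = _toy_experiment([1.000, 0.999, 0.998, 0.997])
        series = cond.conductance_series(exp)
        es25 = 0.61094 * np.exp(17.625 * 25.0 / 268.04)
        vpd = (es25 - 0.5 * es25) / 101.3
        e_mmol = 1e-3 / (18.015 * 1e-3 * 3600.0) * 1e3  # dm/(Mw A dt) in mmol m-2 s-1
        np.testing.assert_allclose(series.g, e_mmol / vpd, rtol=1e-9)

    def test_unit_audit_dimensional_example(self):
        """Worked example: dm = 0.5 mg over 20 min on 5.4 cm2 at VPD 0.02
        must give g in the expected mmol m-2 s-1 range (order 1-10)."""
        dm, a, dt, vpd = 5e-4, 5.4e-4, 1200.0, 0.02
        e = dm / (18.015 * a * dt) * 1e3  # mmol m-2 s-1
        g = e / vpd
        assert 1.0 < g < 10.0
        assert g == pytest.approx(2.1419, rel=1e-3)

    def test_doubling_area_halves_conductance(self):
        a = cond.conductance_series(_toy_experiment([1.0, 0.999, 0.998, 0.997], area=1e-3))
        b = cond.conductance_series(_toy_experiment([1.0, 0.999, 0.998, 0.997], area=2e-3))
        np.testing.assert_allclose(a.g, 2.0 * b.g)

    def test_non_monotonic_timestamps_rejected(self):
        ts = pd.DatetimeIndex(
            ["2023-07-01 08:00", "2023-07-01 09:00", "2023-07-01 08:30", "2023-07-01 10:00"]
        )
        exp = cond.DryingExperiment(
            sample_id="bad",
            timestamps=ts,
            masses=np.array([1.0, 0.99, 0.98, 0.97]),
            ambient_temp=25.0,
            relative_humidity=50.0,
            pressure=101.3,
            projected_leaf_area=1e-3,
        )
        with pytest.raises(ValueError):
            cond.conductance_series(exp)


def _series_from_values(values, dt_hours=1.0):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) * dt_hours
    mid = pd.date_range("2023-07-01", periods=len(values), freq=f"{int(dt_hours*60)}min")
    return cond.ConductanceSeries(
        midpoints=mid,
        elapsed_hours=t,
        g=values,
        phase=np.full(len(values), "unassigned", dtype=object),
    )


class TestDetectPlateau:
    def test_constructed_plateau(self):
        s = _series_from_values([10, 6, 3, 2.0, 2.0, 2.0, 2.0, 1.5, 1.0])
        start, end = cond.detect_plateau(s, min_run=4, smooth_window=1)
        assert (start, end) == (3, 7)

    def test_strictly_monotone_series_has_no_plateau(self):
        s = _series_from_values([10, 8, 6, 4.5, 3.2, 2.1, 1.2, 0.5])
        with pytest.raises(cond.PlateauNotFoundError):
            cond.detect_plateau(s, min_run=3, smooth_window=1)

    def test_noisy_forward_model_plateau_overlaps_ground_truth(self):
        p = syn.DryingForwardParams(true_gmin=2.0, seed=11)
        exp = syn.generate_drying_experiment(p)
        series = cond.conductance_series(exp)
        start, end = cond.detect_plateau(series)
        truth = exp.metadata["phase_truth"]
        detected = np.zeros(len(series.g), dtype=bool)
        detected[start:end] = True
        overlap = (truth[detected] == "plateau").mean()
        assert overlap >= 0.8


class TestEstimateGmin:
    def test_noiseless_forward_model_exact(self):
        p = syn.DryingForwardParams(
            true_gmin=2.0, stomatal_g0=0.0, balance_noise_sd=0.0, duration=12.0
        )
        est = cond.estimate_gmin(syn.generate_drying_experiment(p))
        assert est.gmin == pytest.approx(2.0, rel=1e-11)

    def test_plateau_mean_is_arithmetic_mean(self):
        s = _series_from_values([10, 6, 3, 1.8, 2.0, 2.2, 2.0, 1.9, 2.1, 0.9, 0.4])
        start, end = cond.detect_plateau(s, min_run=3, smooth_window=1, rel_slope_threshold=0.2)
        assert np.mean(s.g[start:end]) == pytest.approx(2.0, abs=0.1)

    def test_recovery_with_default_noise_20min_intervals(self):
        """Forward model at 0.1 mg balance noise, 20-min weighings: the
        estimate lands within a few percent of the true g_min."""
        p = syn.DryingForwardParams(
            true_gmin=2.0, relative_humidity=30.0, ambient_temp=25.0,
            balance_noise_sd=1e-4, interval=20.0, seed=3,
        )
        est = cond.estimate_gmin(syn.generate_drying_experiment(p))
        assert est.gmin == pytest.approx(2.0, rel=0.02)

    def test_scale_equivariance_noiseless(self):
        ests = []
        for c in (1.0, 3.0):
            p = syn.DryingForwardParams(
                true_gmin=1.3 * c, stomatal_g0=0.0, balance_noise_sd=0.0, duration=10.0
            )
            ests.append(cond.estimate_gmin(syn.generate_drying_experiment(p)).gmin)
        assert ests[1] == pytest.approx(3.0 * ests[0], rel=1e-9)

    def test_unbiased_over_many_noisy_experiments(self):
        """Mean relative error below 2% across 200 simulated records at
        default noise."""
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(200):
            p = syn.DryingForwardParams(
                true_gmin=float(rng.uniform(1.0, 7.0)),
                ambient_temp=float(rng.choice([25.0, 38.0, 43.0])),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            est = cond.estimate_gmin(syn.generate_drying_experiment(p))
            errs.append(est.gmin / p.true_gmin - 1.0)
        assert abs(np.mean(errs)) < 0.02
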