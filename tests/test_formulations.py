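"""Emax algebra, steady-state peaks, and trajectory shape invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from occrelapse.formulations import (
    FormulationParams,
    active_trajectory,
    default_formulations,
    dose_from_occupancy,
    load_formulations,
    occupancy_from_dose,
    occupancy_rate,
    placebo_trajectory,
    steady_state_peak,
)


@pytest.fixture(scope="module")
def params():
    return default_formulations()


class TestEmaxAlgebra:
    @pytest.mark.parametrize(
        "dose, expected",
        [(2.38, 50.0), (0.0, 0.0), (9.52, 80.0)],
    )
    def test_occupancy_from_dose(self, params, dose, expected):
        assert occupancy_from_dose(dose, params["lai_1m"]) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "occ, expected",
        [(50.0, 2.38), (0.0, 0.0), (80.0, 9.52)],
    )
    def test_dose_from_occupancy(self, params, occ, expected):
        assert dose_from_occupancy(occ, params["lai_1m"]) == pytest.approx(expected)

    def test_domain_errors(self, params):
        with pytest.raises(ValueError):
            dose_from_occupancy(100.0, params["lai_1m"])  # unreachable occupancy
        with pytest.raises(ValueError):
            occupancy_from_dose(-1.0, params["lai_1m"])

    @given(st.floats(min_value=0.0, max_value=99.999))
    def test_round_trip(self, occ):
        p = default_formulations()["lai_1m"]
        assert occupancy_from_dose(dose_from_occupancy(occ, p), p) == pytest.approx(
            occ, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=1e-6, max_value=1e3))
    def test_monotone_and_bounded(self, dose, delta):
        p = default_formulations()["lai_1m"]
        lo = occupancy_from_dose(dose, p)
        hi = occupancy_from_dose(dose + delta, p)
        assert lo < hi < p.max_occupancy_pct


class TestSteadyStatePeak:
    def test_peak_occupancy_checkpoints(self, params):
        """Peak occupancies round to 86% (1-monthly) and 85% (3-monthly)."""
        occ_1m = occupancy_from_dose(steady_state_peak(params["lai_1m"]), params["lai_1m"])
        occ_3m = occupancy_from_dose(steady_state_peak(params["lai_3m"]), params["lai_3m"])
        assert round(occ_1m) == 86
        assert round(occ_3m) == 85

    def test_zero_decay_time_gives_trough(self):
        p = FormulationParams("lai_1m", 2.38, 37.0, time_to_peak_days=29.999999,
                              dosing_interval_days=30.0)
        assert steady_state_peak(p) == pytest.approx(p.trough_plasma, rel=1e-6)

    def test_oral_unsupported(self, params):
        with pytest.raises(ValueError):
            steady_state_peak(params["oral"])


class TestTrajectories:
    def test_active_injectable_checkpoints(self, params):
        traj = active_trajectory(params["lai_1m"], 90)
        assert traj.occupancy_pct[0] == pytest.approx(80.0)
        assert round(traj.occupancy_pct[5]) == 86  # time to peak
        assert traj.occupancy_pct[30] == pytest.approx(80.0, abs=0.01)

    def test_trough_recurrence_at_dosing_times(self, params):
        for name in ("lai_1m", "lai_3m"):
            p = params[name]
            traj = active_trajectory(p, 487)
            dosing_days = np.arange(0, 488, int(p.dosing_interval_days))
            assert np.allclose(traj.occupancy_pct[dosing_days], 80.0, atol=0.01)

    def test_oral_active_constant(self, params):
        traj = active_trajectory(params["oral"], 365)
        assert np.allclose(traj.occupancy_pct, 80.0)
        assert np.allclose(traj.rate_pct_per_day, 0.0)

    def test_placebo_decay(self, params):
        traj = placebo_trajectory(params["lai_1m"], 365)
        assert traj.occupancy_pct[0] == pytest.approx(80.0)
        # one half-life: plasma 4.76 -> occupancy 4.76/(4.76+2.38)
        assert traj.occupancy_pct[37] == pytest.approx(100 * 4.76 / 7.14, abs=1e-9)
        assert np.all(np.diff(traj.occupancy_pct) < 0)
        assert np.all(occupancy_rate(traj) < 0)

    def test_occupancy_bounded(self, params):
        for p in params.values():
            for traj in (active_trajectory(p, 487), placebo_trajectory(p, 487)):
                assert np.all(traj.occupancy_pct >= 0)
                assert np.all(traj.occupancy_pct < p.max_occupancy_pct)

    def test_rate_matches_analytic_derivative(self, params):
        """Day 0->1 placebo rate ~ chain-rule derivative of Emax o exp decay."""
        p = params["lai_1m"]
        traj = placebo_trajectory(p, 10)
        t_mid = 0.5  # forward difference approximates the midpoint derivative
        plasma = p.trough_plasma * 2.0 ** (-t_mid / p.half_life_days)
        d_occ_d_plasma = 100 * p.ed50_mg_per_day / (plasma + p.ed50_mg_per_day) ** 2
        d_plasma_dt = -np.log(2) / p.half_life_days * plasma
        analytic = d_occ_d_plasma * d_plasma_dt
        assert traj.rate_pct_per_day[0] == pytest.approx(analytic, rel=0.01)

    def test_trough_sensitivity_is_pointwise_monotone(self, params):
        curves = [
            placebo_trajectory(params["lai_1m"].with_trough(t), 365).occupancy_pct
            for t in (75.0, 80.0, 85.0)
        ]
        assert np.all(curves[0] < curves[1])
        assert np.all(curves[1] < curves[2])

    def test_occupancy_decays_slower_than_plasma(self, params):
        traj = placebo_trajectory(params["lai_1m"], 365)
        occ_ratio = traj.occupancy_pct[1:] / traj.occupancy_pct[0]
        plasma_ratio = traj.plasma_equiv[1:] / traj.plasma_equiv[0]
        assert np.all(occ_ratio > plasma_ratio)


class TestParamsValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            FormulationParams("lai_1m", -1.0, 37.0, time_to_peak_days=5,
                              dosing_interval_days=30)
        with pytest.raises(ValueError):
            FormulationParams("lai_1m", 2.38, 37.0, time_to_peak_days=40,
                              dosing_interval_days=30)
        with pytest.raises(ValueError):
            FormulationParams("oral", 2.38, 1.0, trough_occupancy_pct=101)

    def test_config_round_trip(self, tmp_path):
        import yaml

        cfg = {
            "lai_1m": {
                "ed50_mg_per_day": 2.38, "half_life_days": 37.0,
                "time_to_peak_days": 5.0, "dosing_interval_days": 30.0,
                "trough_occupancy_pct": 80.0, "max_occupancy_pct": 100.0,
            }
        }
        path = tmp_path / "f.yaml"
        path.write_text(yaml.safe_dump(cfg))
        loaded = load_formulations(path)
        assert loaded["lai_1m"] == default_formulations()["lai_1m"]

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown formulation keys"):
            load_formulations({"oral": {"ed50": 2.38}})
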