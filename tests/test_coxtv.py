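"""Counting-process construction and the time-varying Cox fitter."""

import numpy as np
import pandas as pd
import pytest

from occrelapse.coxtv import (
    ConvergenceError,
    CoxTimeVaryingModel,
    build_counting_process,
    fit_cox_tv,
    hazard_ratio,
    wald_moderator_test,
)


def _expand_daily(table: pd.DataFrame) -> pd.DataFrame:
    """Split every (start, stop] interval into unit-day rows (test helper)."""
    rows = []
    for _, r in table.iterrows():
        for d in range(int(r["start_day"]), int(r["stop_day"])):
            row = r.copy()
            row["start_day"], row["stop_day"] = d, d + 1
            row["event"] = int(r["event"]) if d + 1 == r["stop_day"] else 0
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def _brute_force_loglik(beta, start, stop, event, x):
    """Independent partial likelihood (untied data) by direct enumeration."""
    ll = 0.0
    for i in np.flatnonzero(event):
        tau = stop[i]
        at_risk = (start < tau) & (tau <= stop)
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


class TestBuildCountingProcess:
    def test_constant_covariates_compress_to_one_row(self, small_trial, lai1m_trajectories):
        table = build_counting_process(small_trial, lai1m_trajectories, ["group"])
        assert len(table) == len(small_trial)
        assert (table["start_day"] == 0).all()
        assert (table["stop_day"].to_numpy() == small_trial["time_days"].to_numpy()).all()

    def test_daily_varying_covariate_rows(self, lai1m_trajectories):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "arm": ["placebo"], "time_days": [3], "event": [1]})
        table = build_counting_process(subjects, lai1m_trajectories, ["group", "occupancy"])
        assert len(table) == 3
        assert table["event"].tolist() == [0, 0, 1]
        assert table["stop_day"].tolist() == [1, 2, 3]

    def test_exposure_conserved(self, small_trial, lai1m_trajectories):
        table = build_counting_process(
            small_trial, lai1m_trajectories, ["group", "occupancy", "rate"])
        exposure = (table["stop_day"] - table["start_day"]).groupby(
            table["subject_id"]).sum()
        expected = small_trial.set_index("subject_id")["time_days"]
        assert (exposure.sort_index() == expected.sort_index()).all()
        assert table["event"].sum() == small_trial["event"].sum()

    def test_horizon_violation_rejected(self, lai1m_trajectories):
        subjects = pd.DataFrame(
            {"subject_id": ["a"], "arm": ["active"], "time_days": [9999], "event": [0]})
        with pytest.raises(ValueError, match="horizon"):
            build_counting_process(subjects, lai1m_trajectories, ["group"])


class TestFitCoxTV:
    def test_matches_grid_search_oracle(self):
        """Newton solution equals dense grid-search argmax on a tiny instance."""
        table = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "start_day": [0, 0, 0, 2, 0, 1],
                "stop_day": [5, 8, 3, 9, 6, 7],
                "event": [1, 0, 1, 1, 0, 1],
                "x": [1.0, 0.2, -0.5, 0.8, -1.0, 0.1],
            }
        )
        fit = fit_cox_tv(table, ["x"])
        grid = np.arange(-3.0, 3.0, 1e-3)
        lls = [
            _brute_force_loglik(b, table["start_day"].to_numpy(),
                                table["stop_day"].to_numpy(),
                                table["event"].to_numpy(), table["x"].to_numpy())
            for b in grid
        ]
        assert fit.params["x"] == pytest.approx(grid[np.argmax(lls)], abs=1e-3)

    def test_compression_is_lossless(self, small_trial, lai1m_trajectories):
        subset = small_trial.groupby("arm").head(60)
        table = build_counting_process(
            subset, lai1m_trajectories, ["group", "occupancy"])
        daily = _expand_daily(table)
        fit_c = fit_cox_tv(table, ["group", "occupancy_pct"])
        fit_d = fit_cox_tv(daily, ["group", "occupancy_pct"])
        assert np.allclose(fit_c.params, fit_d.params, atol=1e-8)
        assert fit_c.llf == pytest.approx(fit_d.llf, abs=1e-8)

    def test_covariate_shift_invariance(self, small_trial, lai1m_trajectories):
        table = build_counting_process(small_trial, lai1m_trajectories,
                                       ["group", "occupancy"])
        fit = fit_cox_tv(table, ["occupancy_pct"])
        shifted = table.assign(occupancy_pct=table["occupancy_pct"] + 17.5)
        fit_s = fit_cox_tv(shifted, ["occupancy_pct"])
        assert fit_s.params["occupancy_pct"] == pytest.approx(
            fit.params["occupancy_pct"], abs=1e-6)

    def test_group_recovery(self, group_effect_trial, lai1m_trajectories):
        """n=2000, true log-HR -1: estimate within +-0.15."""
        table = build_counting_process(group_effect_trial, lai1m_trajectories, ["group"])
        fit = fit_cox_tv(table, ["group"])
        assert fit.params["group"] == pytest.approx(-1.0, abs=0.15)
        hr = hazard_ratio(fit, "group")
        assert hr["hr"] == pytest.approx(np.exp(fit.params["group"]))
        assert hr["lower"] < hr["hr"] < hr["upper"]

    def test_agrees_with_lifelines(self, small_trial, lai1m_trajectories):
        from lifelines import CoxTimeVaryingFitter

        table = build_counting_process(small_trial, lai1m_trajectories,
                                       ["group", "occupancy"])
        table = table.assign(occupancy_per_10pct=table["occupancy_pct"] / 10)
        fit = fit_cox_tv(table, ["group", "occupancy_per_10pct"])
        ll = CoxTimeVaryingFitter()
        ll.fit(
            table.rename(columns={"subject_id": "id"})[
                ["id", "start_day", "stop_day", "event", "group", "occupancy_per_10pct"]],
            id_col="id", start_col="start_day", stop_col="stop_day", event_col="event",
        )
        assert np.allclose(fit.params.to_numpy(), ll.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), ll.standard_errors_.to_numpy(), atol=1e-4)

    def test_separation_diagnostic(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "start_day": [0, 0],
                "stop_day": [1, 2],
                "event": [1, 0],
                "x": [1.0, 0.0],
            }
        )
        with pytest.raises(ConvergenceError, match="separation|diverging"):
            fit_cox_tv(table, ["x"])

    def test_no_events_rejected(self):
        table = pd.DataFrame(
            {"subject_id": ["a", "b"], "start_day": [0, 0], "stop_day": [5, 4],
             "event": [0, 0], "x": [1.0, 0.0]})
        with pytest.raises(ConvergenceError, match="no events"):
            fit_cox_tv(table, ["x"])

    def test_collinear_covariates_rejected(self, small_trial, lai1m_trajectories):
        table = build_counting_process(small_trial, lai1m_trajectories, ["group"])
        table["group2"] = 2 * table["group"]
        with pytest.raises(ValueError, match="collinear"):
            CoxTimeVaryingModel(table, ["group", "group2"])


class TestHazardRatio:
    def test_wald_interval_formula(self):
        from occrelapse.coxtv import CoxTVResults

        idx = pd.Index(["x"])
        fit = CoxTVResults(
            params=pd.Series([0.0], index=idx), bse=pd.Series([0.1], index=idx),
            cov=pd.DataFrame([[0.01]], index=idx, columns=idx), llf=0.0,
            n_events=10, n_intervals=10, converged=True, n_iter=1)
        hr = hazard_ratio(fit, "x")
        assert hr["hr"] == pytest.approx(1.0)
        assert hr["lower"] == pytest.approx(np.exp(-1.96 * 0.1), abs=1e-3)
        assert hr["upper"] == pytest.approx(np.exp(1.96 * 0.1), abs=1e-3)
        with pytest.raises(KeyError):
            hazard_ratio(fit, "y")


class TestModeratorDelegation:
    def test_two_trial_contrast_closed_form(self):
        res = wald_moderator_test([-0.4, -0.9], [0.2, 0.3], ["oral", "lai_1m"])
        z = (-0.9 + 0.4) / np.sqrt(0.04 + 0.09)
        assert res.pairwise[0]["z"] == pytest.approx(-z if
            res.pairwise[0]["levels"] == ["oral", "lai_1m"] else z)
        assert res.q_statistic == pytest.approx(z * z)

    def test_identical_trials_give_null_statistic(self):
        res = wald_moderator_test([-0.5, -0.5], [0.2, 0.2], ["oral", "lai_1m"])
        assert res.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
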