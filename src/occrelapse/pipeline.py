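"""End-to-end analysis pipeline.

Ties the pieces together: configuration, simulation of the five-trial
program, the four relapse analyses —

  (i)   per-trial group hazard ratios plus a formulation moderator test,
  (ii)  case-base time-varying hazard ratios with a pooled group x time
        interaction and an oral-vs-LAI contrast,
  (iii) occupancy rate-of-change models on the LAI trials, pooled,
  (iv)  absolute-occupancy models on the LAI trials, pooled,

— and the trough-occupancy sensitivity re-runs.  Every plotted number also
appears in the JSON report; analyses that cannot run are flagged with a
reason, never silently dropped.
"""

from __future__ import annotations

import datetime
import json
import logging
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .casebase import fit_casebase, pool_interactions, sample_base_series, time_varying_hr
from .coxtv import ConvergenceError, build_counting_process, fit_cox_tv, hazard_ratio
from .formulations import (
    FormulationParams,
    active_trajectory,
    default_formulations,
    load_formulations,
    placebo_trajectory,
    trajectories_frame,
)
from .meta import dl_random_effects, meta_moderator
from .simulate import DEFAULT_DESIGNS, DEFAULT_HAZARD, HazardSpec, TrialDesign, simulate_program

__all__ = [
    "AnalysisConfig",
    "run_trajectories",
    "run_full_analysis",
    "run_sensitivity",
    "save_report",
]

log = logging.getLogger("occrelapse")

SCHEMA_VERSION = 1
LAI_FORMULATIONS = ("lai_1m", "lai_3m")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce a simulation + analysis run."""

    formulations: dict[str, FormulationParams]
    designs: tuple[TrialDesign, ...]
    hazard: HazardSpec
    trough_occupancy_grid: tuple[float, ...] = (75.0, 80.0, 85.0)
    base_ratio: float = 100.0
    occupancy_scale_pct: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for t in self.trough_occupancy_grid:
            for p in self.formulations.values():
                if not 0 < t < p.max_occupancy_pct:
                    raise ValueError(
                        f"trough grid value {t} outside (0, {p.max_occupancy_pct})")

    @classmethod
    def default(cls, seed: int | None = None) -> "AnalysisConfig":
        return cls(
            formulations=default_formulations(),
            designs=DEFAULT_DESIGNS,
            hazard=DEFAULT_HAZARD,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "AnalysisConfig":
        try:
            formulations = load_formulations(raw["formulations"])
            designs = tuple(TrialDesign(**d) for d in raw["trials"])
            hazard = HazardSpec(**raw.get("hazard", {}))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"invalid analysis config: {exc}") from exc
        analysis = raw.get("analysis", {})
        return cls(
            formulations=formulations,
            designs=designs,
            hazard=hazard,
            trough_occupancy_grid=tuple(
                analysis.get("trough_occupancy_grid", (75.0, 80.0, 85.0))),
            base_ratio=float(analysis.get("base_ratio", 100.0)),
            occupancy_scale_pct=float(analysis.get("occupancy_scale_pct", 10.0)),
            seed=raw.get("seed"),
        )

    def design_for(self, trial_id: str) -> TrialDesign:
        for d in self.designs:
            if d.trial_id == trial_id:
                return d
        raise KeyError(f"unknown trial_id {trial_id!r}")

    def simulate(self, seed: int | None = None) -> pd.DataFrame:
        seed = self.seed if seed is None else seed
        if seed is None:
            raise ValueError("a master seed is required to simulate")
        return simulate_program(self.designs, self.formulations, self.hazard, seed)


def default_config_path() -> Path:
    return Path(resources.files("occrelapse") / "data" / "default_config.yaml")


# ---------------------------------------------------------------------------
# Analysis helpers
# ---------------------------------------------------------------------------

def _trial_trajectories(config: AnalysisConfig, design: TrialDesign, trough: float):
    params = config.formulations[design.formulation].with_trough(trough)
    horizon = design.max_followup_days
    return {
        "active": active_trajectory(params, horizon),
        "placebo": placebo_trajectory(params, horizon),
    }


def _skip(reason: str) -> dict:
    return {"skipped": True, "reason": reason}


def _fit_trial_cox(subjects, trajectories, covariates, model_cols, occupancy_scale):
    table = build_counting_process(subjects, trajectories, covariates)
    if "occupancy_pct" in table.columns:
        table[f"occupancy_per_{occupancy_scale:g}pct"] = (
            table["occupancy_pct"] / occupancy_scale)
    return fit_cox_tv(table, model_cols)


def _per_trial_cox(config, data, trough, covariates, model_cols, trial_ids):
    """Fit one Cox specification per trial, collecting failures as skips."""
    fits, entries = {}, {}
    for tid in trial_ids:
        design = config.design_for(tid)
        subjects = data[data["trial_id"] == tid]
        if subjects.empty:
            entries[tid] = _skip("no subjects")
            continue
        if subjects["event"].sum() == 0:
            entries[tid] = _skip("no relapse events")
            continue
        if subjects["arm"].nunique() < 2:
            entries[tid] = _skip("single-arm trial")
            continue
        traj = _trial_trajectories(config, design, trough)
        try:
            fit = _fit_trial_cox(subjects, traj, covariates, model_cols,
                                 config.occupancy_scale_pct)
        except (ConvergenceError, ValueError) as exc:
            entries[tid] = _skip(str(exc))
            continue
        fits[tid] = fit
        entry = fit.to_dict()
        entry["formulation"] = design.formulation
        entry["hazard_ratios"] = {c: hazard_ratio(fit, c) for c in model_cols}
        entries[tid] = entry
        log.info("cox fit trial=%s covs=%s events=%d iters=%d",
                 tid, model_cols, fit.n_events, fit.n_iter)
    return fits, entries


def _pool_by_formulation(config, fits: dict, coefficient: str) -> dict:
    """DL pooling of one coefficient within each formulation and LAI-combined."""
    by_form: dict[str, list] = {}
    for tid, fit in fits.items():
        form = config.design_for(tid).formulation
        by_form.setdefault(form, []).append(
            (float(fit.params[coefficient]), float(fit.bse[coefficient])))
    out = {}
    for form, pairs in sorted(by_form.items()):
        est, ses = zip(*pairs)
        out[form] = dl_random_effects(est, ses).to_dict()
    lai_pairs = [p for f in LAI_FORMULATIONS for p in by_form.get(f, [])]
    if lai_pairs:
        est, ses = zip(*lai_pairs)
        out["lai_combined"] = dl_random_effects(est, ses).to_dict()
    return out


# ---------------------------------------------------------------------------
# Pipeline entry points
# ---------------------------------------------------------------------------

def run_trajectories(config: AnalysisConfig, out_dir: str | Path | None = None,
                     trough: float | None = None) -> pd.DataFrame:
    """All six (formulation x arm) trajectories over the longest trial horizon."""
    trough = trough if trough is not None else config.formulations["oral"].trough_occupancy_pct
    horizon = max(d.max_followup_days for d in config.designs)
    params = {k: v.with_trough(trough) for k, v in config.formulations.items()}
    frame = trajectories_frame(params, horizon)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "trajectories.csv", index=False)
        _plot_trajectories(frame, params, out_dir / "trajectories.png")
    return frame


def run_full_analysis(config: AnalysisConfig, data: pd.DataFrame | str = "simulate",
                      seed: int | None = None, trough: float | None = None) -> dict:
    """Run analyses (i)-(iv) and assemble the JSON-serialisable report."""
    seed = config.seed if seed is None else seed
    if isinstance(data, str):
        if data != "simulate":
            raise ValueError("data must be a patient frame or the string 'simulate'")
        data = config.simulate(seed)
    trough = (trough if trough is not None
              else config.formulations["oral"].trough_occupancy_pct)
    trial_ids = [d.trial_id for d in config.designs if d.trial_id in set(data["trial_id"])]
    lai_ids = [t for t in trial_ids
               if config.design_for(t).formulation in LAI_FORMULATIONS]
    oral_ids = [t for t in trial_ids if t not in lai_ids]

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "trough_occupancy_pct": trough,
        "n_subjects": int(len(data)),
        "n_events": int(data["event"].sum()),
        "trials": {
            tid: {
                "formulation": config.design_for(tid).formulation,
                "n": int((data["trial_id"] == tid).sum()),
                "n_events": int(data.loc[data["trial_id"] == tid, "event"].sum()),
            }
            for tid in trial_ids
        },
        "analyses": {},
    }

    # (i) group effect per trial + formulation moderator
    fits_i, entries_i = _per_trial_cox(
        config, data, trough, ["group"], ["group"], trial_ids)
    analysis_i: dict = {"per_trial": entries_i}
    if fits_i:
        analysis_i["pooled_by_formulation"] = _pool_by_formulation(config, fits_i, "group")
        labels = [config.design_for(t).formulation for t in fits_i]
        if len(set(labels)) >= 2:
            analysis_i["moderator"] = meta_moderator(
                [float(f.params["group"]) for f in fits_i.values()],
                [float(f.bse["group"]) for f in fits_i.values()],
                labels,
            ).to_dict()
        else:
            analysis_i["moderator"] = _skip("fewer than two formulation levels fitted")
    else:
        analysis_i = _skip("no trial could be fitted")
    report["analyses"]["group"] = analysis_i

    # (ii) case-base time-varying hazard ratio
    entries_ii: dict = {}
    cb_fits, cb_labels = [], []
    ss = np.random.SeedSequence([0 if seed is None else int(seed), 2])
    trial_seeds = {tid: s for tid, s in zip(trial_ids, ss.spawn(len(trial_ids)))}
    for tid in trial_ids:
        subjects = data[data["trial_id"] == tid]
        form = config.design_for(tid).formulation
        try:
            sample = sample_base_series(
                subjects, config.base_ratio, np.random.default_rng(trial_seeds[tid]))
            fit = fit_casebase(sample, include_interaction=True)
        except (ValueError, RuntimeError) as exc:
            entries_ii[tid] = _skip(str(exc))
            continue
        cb_fits.append(fit)
        cb_labels.append("oral" if form == "oral" else "lai")
        entry = fit.to_dict()
        entry["formulation"] = form
        entry["hr_at"] = {str(d): time_varying_hr(fit, d) for d in (0, 90, 180, 365)}
        entries_ii[tid] = entry
    analysis_ii: dict = {"per_trial": entries_ii}
    if len(cb_fits) >= 2:
        if len(set(cb_labels)) >= 2:
            pooled, contrast = pool_interactions(cb_fits, cb_labels)
            analysis_ii["oral_vs_lai"] = contrast.to_dict()
        else:
            pooled = pool_interactions(cb_fits)
            analysis_ii["oral_vs_lai"] = _skip("only one formulation class fitted")
        analysis_ii["pooled_interaction"] = pooled.to_dict()
    elif cb_fits:
        analysis_ii["pooled_interaction"] = _skip("fewer than two case-base fits")
        analysis_ii["oral_vs_lai"] = _skip("fewer than two case-base fits")
    else:
        analysis_ii = _skip("no case-base fit possible")
    report["analyses"]["time_interaction"] = analysis_ii

    # (iii) occupancy rate of change, LAI trials only
    report["analyses"]["rate"] = _lai_covariate_analysis(
        config, data, trough, lai_ids, oral_ids,
        covariates=["group", "rate"],
        model_cols=["group", "rate_pct_per_day"],
        coefficient="rate_pct_per_day",
    )

    # (iv) absolute occupancy, LAI trials only
    occ_col = f"occupancy_per_{config.occupancy_scale_pct:g}pct"
    report["analyses"]["occupancy"] = _lai_covariate_analysis(
        config, data, trough, lai_ids, oral_ids,
        covariates=["group", "occupancy"],
        model_cols=["group", occ_col],
        coefficient=occ_col,
    )
    return report


def _lai_covariate_analysis(config, data, trough, lai_ids, oral_ids,
                            covariates, model_cols, coefficient) -> dict:
    if not lai_ids:
        return _skip("no LAI trials present (oral trials are excluded from "
                     "occupancy-based analyses)")
    fits, entries = _per_trial_cox(config, data, trough, covariates, model_cols, lai_ids)
    out: dict = {
        "per_trial": entries,
        "excluded_trials": list(oral_ids),
        "k": len(fits),
        "coefficient": coefficient,
    }
    if fits:
        out["pooled_by_formulation"] = _pool_by_formulation(config, fits, coefficient)
    else:
        out["pooled_by_formulation"] = _skip("no LAI trial could be fitted")
    return out


def run_sensitivity(config: AnalysisConfig, data: pd.DataFrame | str = "simulate",
                    seed: int | None = None) -> dict:
    """Repeat the full analysis at each trough-occupancy grid value.

    When ``data`` is a frame the subject records are held fixed and only the
    analysis covariate trajectories change with the trough assumption.
    """
    if len(config.trough_occupancy_grid) < 2:
        raise ValueError("sensitivity analysis needs a trough grid with >= 2 values")
    seed = config.seed if seed is None else seed
    if isinstance(data, str):
        data = config.simulate(seed)
    reports = {}
    for trough in config.trough_occupancy_grid:
        reports[f"{trough:g}"] = run_full_analysis(config, data, seed=seed, trough=trough)
    comparison = []
    for trough, rep in reports.items():
        row = {"trough_occupancy_pct": float(trough)}
        for name in ("rate", "occupancy"):
            block = rep["analyses"][name]
            pooled = block.get("pooled_by_formulation", {}) if not block.get("skipped") else {}
            lai = pooled.get("lai_combined") if isinstance(pooled, dict) else None
            if lai and not lai.get("skipped"):
                row[f"{name}_pooled_lai"] = lai["pooled_estimate"]
                row[f"{name}_pooled_lai_se"] = lai["pooled_se"]
        block = rep["analyses"]["time_interaction"]
        if not block.get("skipped") and not block.get("pooled_interaction", {}).get("skipped"):
            row["time_interaction_pooled"] = block["pooled_interaction"]["pooled_estimate"]
        comparison.append(row)
    return {"troughs": reports, "comparison": comparison}


def save_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _plot_trajectories(frame: pd.DataFrame, params, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, arm in zip(axes, ("active", "placebo")):
        for form, sub in frame[frame["arm"] == arm].groupby("formulation"):
            ax.plot(sub["day"], sub["occupancy_pct"], label=form)
        ax.set_title(f"{arm} arm")
        ax.set_xlabel("days since randomization")
        ax.set_ylim(0, 100)
    axes[0].set_ylabel("D2 receptor occupancy (%)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(report: dict, path: str | Path) -> None:
    """Forest-style display of per-trial and pooled log-hazard-ratios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for analysis, coef in (("group", "group"), ("rate", None), ("occupancy", None)):
        block = report["analyses"].get(analysis, {})
        if block.get("skipped"):
            continue
        coef = coef or block.get("coefficient")
        for tid, entry in block.get("per_trial", {}).items():
            if entry.get("skipped"):
                continue
            b = entry["coefficients"][coef]
            se = entry["standard_errors"][coef]
            rows.append((f"{analysis}: {tid}", b, se))
        pooled = block.get("pooled_by_formulation", {})
        if isinstance(pooled, dict):
            lai = pooled.get("lai_combined")
            if lai and not lai.get("skipped"):
                rows.append((f"{analysis}: LAI combined", lai["pooled_estimate"],
                             lai["pooled_se"]))
    if not rows:
        return
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(rows) + 1.5))
    y = np.arange(len(rows))[::-1]
    for yi, (label, b, se) in zip(y, rows):
        ax.errorbar(b, yi, xerr=1.96 * se, fmt="o", color="k", capsize=3)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([r[0] for r in rows])
    ax.set_xlabel("log hazard ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
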