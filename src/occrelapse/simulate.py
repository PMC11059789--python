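"""Synthetic discontinuation-trial generator.

Emulates a program of five parallel-group, placebo-controlled relapse
prevention trials (two oral, two 1-monthly injectable, one 3-monthly
injectable) whose per-day relapse hazards are driven by the arm-level
occupancy trajectories:

    h(t) = h0 * exp(b_group * 1[active]
                    + b_occ * occ(t) / 10
                    + b_rate * rate(t)
                    + b_interaction * 1[active] * t)

Event days are drawn by discrete inverse transform on the accumulated daily
hazard; dropout is independent exponential censoring rounded up to whole
days; administrative censoring applies at the trial's maximum follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formulations import (
    FormulationParams,
    OccupancyTrajectory,
    active_trajectory,
    placebo_trajectory,
)

__all__ = [
    "TrialDesign",
    "HazardSpec",
    "DEFAULT_DESIGNS",
    "DEFAULT_HAZARD",
    "daily_hazard",
    "simulate_subject",
    "simulate_trial",
    "simulate_program",
]

SUBJECT_COLUMNS = ["subject_id", "trial_id", "formulation", "arm", "time_days", "event"]


@dataclass(frozen=True)
class TrialDesign:
    """Structure of one parallel-group discontinuation trial."""

    trial_id: str
    formulation: str
    n_active: int
    n_placebo: int
    max_followup_days: int
    dropout_hazard_per_day: float = 0.0006

    def __post_init__(self) -> None:
        if self.n_active < 0 or self.n_placebo < 0 or self.n_active + self.n_placebo < 2:
            raise ValueError("need n_active, n_placebo >= 0 with total >= 2")
        if self.max_followup_days < 1:
            raise ValueError("max_followup_days must be >= 1")
        if self.dropout_hazard_per_day < 0:
            raise ValueError("dropout_hazard_per_day must be nonnegative")


@dataclass(frozen=True)
class HazardSpec:
    """Generative ground truth for the relapse hazard."""

    baseline_hazard_per_day: float = 0.005
    beta_group: float = 0.0
    beta_occ_per_10pct: float = -0.34
    beta_rate: float = 0.0
    beta_time_interaction_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_hazard_per_day <= 0:
            raise ValueError("baseline_hazard_per_day must be positive")
        for b in (self.beta_group, self.beta_occ_per_10pct, self.beta_rate,
                  self.beta_time_interaction_per_day):
            if not np.isfinite(b):
                raise ValueError("hazard coefficients must be finite")


# Default program mirrors the five-trial structure: arm sizes and follow-up
# horizons of the 3-monthly LAI, two 1-monthly LAI, and two oral studies
# ("up to 16 months" -> 487 d, "up to 14 months" -> 426 d, "up to 12" -> 365 d
# at 30.4375 days/month).
DEFAULT_DESIGNS = (
    TrialDesign("lai3m_A", "lai_3m", 159, 144, 487),
    TrialDesign("lai1m_A", "lai_1m", 164, 170, 487),
    TrialDesign("lai1m_B", "lai_1m", 205, 203, 487),
    TrialDesign("oral_A", "oral", 105, 102, 365),
    TrialDesign("oral_B", "oral", 65, 71, 426),
)

DEFAULT_HAZARD = HazardSpec()


def daily_hazard(arm: str, day, traj: OccupancyTrajectory, spec: HazardSpec):
    """Per-day relapse hazard over the interval (day, day+1]."""
    day = np.asarray(day)
    if np.any(day < 0) or np.any(day > traj.horizon_days):
        raise ValueError("day outside trajectory grid")
    is_active = 1.0 if arm == "active" else 0.0
    lp = (
        spec.beta_group * is_active
        + spec.beta_occ_per_10pct * traj.occupancy_pct[day] / 10.0
        + spec.beta_rate * traj.rate_pct_per_day[day]
        + spec.beta_time_interaction_per_day * is_active * day
    )
    out = spec.baseline_hazard_per_day * np.exp(lp)
    return float(out) if out.ndim == 0 else out


def _cumulative_hazard(arm: str, traj: OccupancyTrajectory, spec: HazardSpec,
                       horizon: int) -> np.ndarray:
    """Lambda(t) for t = 0..horizon: hazard accumulated over days 0..t-1."""
    h = daily_hazard(arm, np.arange(horizon), traj, spec)
    return np.concatenate([[0.0], np.cumsum(h)])


def _sample_times(arm: str, n: int, design: TrialDesign, traj: OccupancyTrajectory,
                  spec: HazardSpec, rng: np.random.Generator):
    """Vectorised observed times and event flags for ``n`` subjects of one arm."""
    horizon = design.max_followup_days
    if traj.horizon_days < horizon:
        raise ValueError("trajectory horizon shorter than trial follow-up")
    cumhaz = _cumulative_hazard(arm, traj, spec, horizon)
    # relapse at the first day t in 1..horizon with Lambda(t) >= Exp(1) draw
    e = rng.exponential(size=n)
    relapse_day = np.searchsorted(cumhaz, e, side="left")  # horizon+? -> no relapse
    relapse_day = np.where(relapse_day > horizon, horizon + 1, relapse_day)
    if design.dropout_hazard_per_day > 0:
        dropout = np.ceil(rng.exponential(1.0 / design.dropout_hazard_per_day, size=n))
    else:
        dropout = np.full(n, np.inf)
    censor_day = np.minimum(dropout, horizon)
    time = np.minimum(relapse_day, censor_day).astype(int)
    event = (relapse_day <= censor_day).astype(int)  # relapse wins day ties
    return time, event


def simulate_subject(arm: str, design: TrialDesign, traj: OccupancyTrajectory,
                     spec: HazardSpec, rng: np.random.Generator) -> dict:
    """One subject record (arm, observed follow-up days, event flag)."""
    time, event = _sample_times(arm, 1, design, traj, spec, rng)
    return {
        "trial_id": design.trial_id,
        "formulation": design.formulation,
        "arm": arm,
        "time_days": int(time[0]),
        "event": int(event[0]),
    }


def simulate_trial(design: TrialDesign, params: FormulationParams, spec: HazardSpec,
                   seed: int | np.random.SeedSequence) -> pd.DataFrame:
    """Simulate one trial; returns a patient-level frame (one row per subject)."""
    if params.name != design.formulation:
        raise ValueError("formulation parameters do not match trial design")
    rng = np.random.default_rng(seed)
    horizon = design.max_followup_days
    act = active_trajectory(params, horizon)
    plc = placebo_trajectory(params, horizon)
    t_a, e_a = _sample_times("active", design.n_active, design, act, spec, rng)
    t_p, e_p = _sample_times("placebo", design.n_placebo, design, plc, spec, rng)
    n = design.n_active + design.n_placebo
    return pd.DataFrame(
        {
            "subject_id": [f"{design.trial_id}_{i:04d}" for i in range(1, n + 1)],
            "trial_id": design.trial_id,
            "formulation": design.formulation,
            "arm": ["active"] * design.n_active + ["placebo"] * design.n_placebo,
            "time_days": np.concatenate([t_a, t_p]),
            "event": np.concatenate([e_a, e_p]),
        }
    )


def simulate_program(designs: Sequence[TrialDesign],
                     params_by_name: Mapping[str, FormulationParams],
                     spec: HazardSpec,
                     seed: int) -> pd.DataFrame:
    """Simulate a multi-trial program with per-trial seeds spawned from ``seed``."""
    if len(designs) < 1:
        raise ValueError("need at least one trial design")
    ids = [d.trial_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial_id in designs")
    child_seeds = np.random.SeedSequence(seed).spawn(len(designs))
    frames = [
        simulate_trial(d, params_by_name[d.formulation], spec, s)
        for d, s in zip(designs, child_seeds)
    ]
    return pd.concat(frames, ignore_index=True)[SUBJECT_COLUMNS]
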