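"""D2 receptor-occupancy trajectories for paliperidone formulations.

The pharmacodynamic core is a saturating Emax relation between a plasma-level
dose-equivalent ``d`` (mg/day) and striatal D2 receptor occupancy (percent)::

    occupancy = max_occupancy * d / (d + ED50)

Stabilised patients are assumed to sit at a trough occupancy (default 80%) at
randomization.  For long-acting injectables the active arm follows a periodic
sawtooth in plasma equivalent -- linear rise from trough to the steady-state
peak over the time-to-peak, then first-order decay back to the trough over the
rest of the dosing interval -- while the placebo arm decays exponentially from
the trough with the formulation's apparent half-life.  Oral active treatment is
represented as a constant daily-average plasma level; oral placebo washes out
with a short (default one-day) half-life.

All trajectories live on an integer daily grid with day 0 = randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormulationParams",
    "OccupancyTrajectory",
    "DEFAULT_FORMULATIONS",
    "default_formulations",
    "load_formulations",
    "occupancy_from_dose",
    "dose_from_occupancy",
    "steady_state_peak",
    "active_trajectory",
    "placebo_trajectory",
    "occupancy_rate",
    "trajectories_frame",
]

ORAL = "oral"
LAI_1M = "lai_1m"
LAI_3M = "lai_3m"
FORMULATIONS = (ORAL, LAI_1M, LAI_3M)


@dataclass(frozen=True)
class FormulationParams:
    """Pharmacokinetic/pharmacodynamic constants for one formulation.

    Parameters
    ----------
    name
        One of ``"oral"``, ``"lai_1m"``, ``"lai_3m"``.
    ed50_mg_per_day
        Plasma dose-equivalent producing half-maximal occupancy (mg/day).
    half_life_days
        Apparent elimination half-life.  For the oral formulation this governs
        only the placebo washout (oral active is modelled as constant).
    time_to_peak_days, dosing_interval_days
        Injection-cycle shape parameters; ``None`` for oral.
    trough_occupancy_pct
        Occupancy at the dosing trough / point of randomization.
    max_occupancy_pct
        Asymptote of the Emax relation (default 100).
    """

    name: str
    ed50_mg_per_day: float
    half_life_days: float
    trough_occupancy_pct: float = 80.0
    max_occupancy_pct: float = 100.0
    time_to_peak_days: float | None = None
    dosing_interval_days: float | None = None

    def __post_init__(self) -> None:
        if self.ed50_mg_per_day <= 0:
            raise ValueError("ed50_mg_per_day must be positive")
        if self.half_life_days <= 0:
            raise ValueError("half_life_days must be positive")
        if not 0 < self.trough_occupancy_pct < self.max_occupancy_pct <= 100:
            raise ValueError(
                "require 0 < trough_occupancy_pct < max_occupancy_pct <= 100"
            )
        if self.is_injectable:
            if self.time_to_peak_days is None or self.dosing_interval_days is None:
                raise ValueError(
                    "injectable formulations need time_to_peak_days and "
                    "dosing_interval_days"
                )
            if not 0 < self.time_to_peak_days < self.dosing_interval_days:
                raise ValueError("require 0 < time_to_peak_days < dosing_interval_days")

    @property
    def is_injectable(self) -> bool:
        return self.name != ORAL

    @property
    def trough_plasma(self) -> float:
        """Plasma dose-equivalent at the trough occupancy."""
        return dose_from_occupancy(self.trough_occupancy_pct, self)

    def with_trough(self, trough_occupancy_pct: float) -> "FormulationParams":
        """Copy with a different trough occupancy (sensitivity analyses)."""
        return replace(self, trough_occupancy_pct=trough_occupancy_pct)


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Daily plasma-equivalent and occupancy series for one arm.

    ``rate_pct_per_day`` is the forward first difference of ``occupancy_pct``
    assigned to the start day of each one-day interval; the final grid point
    carries the last defined difference.
    """

    formulation: str
    arm: str  # "active" | "placebo"
    time_days: np.ndarray = field(repr=False)
    plasma_equiv: np.ndarray = field(repr=False)
    occupancy_pct: np.ndarray = field(repr=False)
    rate_pct_per_day: np.ndarray = field(repr=False)

    @property
    def horizon_days(self) -> int:
        return int(self.time_days[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "formulation": self.formulation,
                "arm": self.arm,
                "day": self.time_days,
                "plasma_equiv": self.plasma_equiv,
                "occupancy_pct": self.occupancy_pct,
                "rate_pct_per_day": self.rate_pct_per_day,
            }
        )


# ---------------------------------------------------------------------------
# Emax algebra
# ---------------------------------------------------------------------------

def occupancy_from_dose(dose, params: FormulationParams):
    """Occupancy (%) at a plasma dose-equivalent via the Emax relation."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be nonnegative")
    out = params.max_occupancy_pct * dose / (dose + params.ed50_mg_per_day)
    return float(out) if out.ndim == 0 else out


def dose_from_occupancy(occ_pct, params: FormulationParams):
    """Invert the Emax relation: plasma dose-equivalent giving ``occ_pct``."""
    occ = np.asarray(occ_pct, dtype=float)
    if np.any(occ < 0) or np.any(occ >= params.max_occupancy_pct):
        raise ValueError(
            f"occupancy must lie in [0, {params.max_occupancy_pct}) to be reachable"
        )
    out = params.ed50_mg_per_day * occ / (params.max_occupancy_pct - occ)
    return float(out) if out.ndim == 0 else out


def steady_state_peak(params: FormulationParams) -> float:
    """Steady-state peak plasma dose-equivalent for an injectable.

    First-order decay from the peak over the (interval - time_to_peak) days
    remaining after the peak must land exactly on the trough level, so

        peak = trough_plasma * 2 ** ((interval - t_peak) / half_life)
    """
    if not params.is_injectable:
        raise ValueError("steady_state_peak is defined for injectables only")
    decay_days = params.dosing_interval_days - params.time_to_peak_days
    return params.trough_plasma * 2.0 ** (decay_days / params.half_life_days)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _finish(params: FormulationParams, arm: str, days: np.ndarray,
            plasma: np.ndarray) -> OccupancyTrajectory:
    occ = occupancy_from_dose(plasma, params)
    return OccupancyTrajectory(
        formulation=params.name,
        arm=arm,
        time_days=days,
        plasma_equiv=plasma,
        occupancy_pct=occ,
        rate_pct_per_day=_forward_rate(occ),
    )


def _forward_rate(occ: np.ndarray) -> np.ndarray:
    if occ.size < 2:
        raise ValueError("rate requires at least two grid points")
    diff = np.diff(occ)
    return np.concatenate([diff, diff[-1:]])


def active_trajectory(params: FormulationParams, horizon_days: int) -> OccupancyTrajectory:
    """Active-arm trajectory on days 0..horizon.

    Injectables: periodic sawtooth (an injection is given at randomization,
    day 0, with plasma at trough).  Oral: constant daily-average plasma.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    days = np.arange(horizon_days + 1)
    trough = params.trough_plasma
    if not params.is_injectable:
        plasma = np.full(days.shape, trough)
        return _finish(params, "active", days, plasma)

    peak = steady_state_peak(params)
    u = days % params.dosing_interval_days
    rising = u <= params.time_to_peak_days
    plasma = np.where(
        rising,
        trough + (peak - trough) * u / params.time_to_peak_days,
        peak * 2.0 ** (-(u - params.time_to_peak_days) / params.half_life_days),
    )
    return _finish(params, "active", days, plasma)


def placebo_trajectory(params: FormulationParams, horizon_days: int) -> OccupancyTrajectory:
    """Placebo-arm trajectory: first-order decay from the randomization trough."""
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    days = np.arange(horizon_days + 1)
    plasma = params.trough_plasma * 2.0 ** (-days / params.half_life_days)
    return _finish(params, "placebo", days, plasma)


def occupancy_rate(traj: OccupancyTrajectory) -> np.ndarray:
    """Daily rate of occupancy change (% per day): forward first difference."""
    return _forward_rate(traj.occupancy_pct)


def trajectories_frame(params_by_name: Mapping[str, FormulationParams],
                       horizon_days: int) -> pd.DataFrame:
    """Tidy frame of all (formulation x arm) trajectories for export/plotting."""
    frames = []
    for params in params_by_name.values():
        frames.append(active_trajectory(params, horizon_days).to_frame())
        frames.append(placebo_trajectory(params, horizon_days).to_frame())
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Default parameter profiles and config I/O
# ---------------------------------------------------------------------------

def default_formulations(trough_occupancy_pct: float = 80.0) -> dict[str, FormulationParams]:
    """Bundled formulation profiles.

    ED50 2.38 mg/day and maximal occupancy 100% throughout.  The oral
    ``half_life_days`` of 1.0 governs only the placebo washout; oral active
    treatment is modelled as a constant daily average.
    """
    t = trough_occupancy_pct
    return {
        ORAL: FormulationParams(ORAL, 2.38, 1.0, trough_occupancy_pct=t),
        LAI_1M: FormulationParams(
            LAI_1M, 2.38, 37.0, trough_occupancy_pct=t,
            time_to_peak_days=5.0, dosing_interval_days=30.0),
        LAI_3M: FormulationParams(
            LAI_3M, 2.38, 111.5, trough_occupancy_pct=t,
            time_to_peak_days=28.0, dosing_interval_days=90.0),
    }


DEFAULT_FORMULATIONS = default_formulations()

_CONFIG_KEYS = {
    "ed50_mg_per_day", "half_life_days", "time_to_peak_days",
    "dosing_interval_days", "trough_occupancy_pct", "max_occupancy_pct",
}


def load_formulations(source: str | Path | Mapping) -> dict[str, FormulationParams]:
    """Read formulation parameter blocks from a YAML/JSON mapping or file."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if "formulations" in source:
        source = source["formulations"]
    out = {}
    for name, block in source.items():
        bad = set(block) - _CONFIG_KEYS
        if bad:
            raise ValueError(f"unknown formulation keys for {name!r}: {sorted(bad)}")
        out[name] = FormulationParams(name=name, **block)
    return out
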