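"""Case-base sampled smooth-in-time hazard estimation.

The hazard is estimated by contrasting the "case series" (the person-moments
at which relapses occurred) with a "base series" of person-moments sampled
uniformly over the observed person-time, in a logistic model.  With b base
moments over B person-days, the log-odds of a sampled moment being a case
approximate

    log h(t) + log(B / b)

so a logistic fit of case status on (group, day, group x day) estimates the
log-hazard's dependence on treatment and time; the sampling constant
log(B / b) is absorbed by the intercept and subtracted whenever an absolute
log-hazard is reported.  A linear group x day interaction makes the
log hazard ratio vary linearly in time, relaxing the proportional-hazards
constraint of the Cox model.

Base moments are sampled with replacement (the Hanley-Miettinen convention);
case moments are never removed from the base distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .meta import dl_random_effects, meta_moderator

__all__ = [
    "PersonMomentSample",
    "CaseBaseResults",
    "CaseBaseHazardModel",
    "sample_base_series",
    "fit_casebase",
    "time_varying_hr",
    "pool_interactions",
]


@dataclass(frozen=True)
class PersonMomentSample:
    """Case and base person-moments drawn from subject follow-up."""

    moments: pd.DataFrame = field(repr=False)  # subject_id, day, is_case, group
    base_size: int
    total_person_time: float
    offset: float  # log(total_person_time / base_size)

    @property
    def n_cases(self) -> int:
        return int(self.moments["is_case"].sum())


def sample_base_series(subjects: pd.DataFrame, base_ratio: float,
                       rng: np.random.Generator | int) -> PersonMomentSample:
    """Draw the case series plus ``base_ratio`` base moments per case.

    Base moments: a subject is chosen with probability proportional to its
    observed follow-up and a day uniformly within that follow-up (with
    replacement).  Case moments are the event days of relapsing subjects.
    """
    if base_ratio < 1:
        raise ValueError("base_ratio must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = subjects["time_days"].to_numpy(dtype=int)
    events = subjects["event"].to_numpy(dtype=int)
    group = (subjects["arm"].to_numpy() == "active").astype(int)
    sid = subjects["subject_id"].to_numpy()
    n_cases = int(events.sum())
    if n_cases == 0:
        raise ValueError("no events: case series is empty")
    total_pt = float(times.sum())
    b = int(round(base_ratio * n_cases))
    # subject ~ follow-up-weighted, day ~ uniform integer in 1..time
    pick = rng.choice(len(times), size=b, p=times / total_pt)
    base_day = rng.integers(1, times[pick] + 1)
    case_rows = np.flatnonzero(events == 1)
    moments = pd.DataFrame(
        {
            "subject_id": np.concatenate([sid[case_rows], sid[pick]]),
            "day": np.concatenate([times[case_rows], base_day]),
            "is_case": np.concatenate([np.ones(n_cases, int), np.zeros(b, int)]),
            "group": np.concatenate([group[case_rows], group[pick]]),
        }
    )
    return PersonMomentSample(
        moments=moments,
        base_size=b,
        total_person_time=total_pt,
        offset=float(np.log(total_pt / b)),
    )


@dataclass
class CaseBaseResults:
    """Fitted smooth-in-time hazard model.

    ``params`` holds ``intercept``, ``group``, ``day`` and (optionally)
    ``group_x_day``; the intercept includes the sampling constant, so the
    absolute log-hazard at a moment is the linear predictor minus ``offset``.
    """

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    offset: float
    converged: bool
    n_cases: int
    include_interaction: bool

    @property
    def beta_group(self) -> float:
        return float(self.params["group"])

    @property
    def beta_time(self) -> float:
        return float(self.params["day"])

    @property
    def beta_interaction(self) -> float:
        return float(self.params["group_x_day"]) if self.include_interaction else 0.0

    def log_hazard(self, group: int, day: float) -> float:
        """Absolute log daily hazard at (group, day)."""
        x = self.params["intercept"] + self.params["group"] * group + self.params["day"] * day
        if self.include_interaction:
            x += self.params["group_x_day"] * group * day
        return float(x - self.offset)

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            {"coef": self.params, "se(coef)": self.bse, "z": z,
             "p": 2 * stats.norm.sf(np.abs(z))})

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "covariance": self.cov.to_numpy().tolist(),
            "offset": self.offset,
            "converged": self.converged,
            "n_cases": self.n_cases,
        }


class CaseBaseHazardModel:
    """Logistic case-vs-base model of the smooth-in-time hazard."""

    def __init__(self, sample: PersonMomentSample, include_interaction: bool = True):
        m = sample.moments
        for g in (0, 1):
            sub = m[m["group"] == g]
            if len(sub) == 0 or sub["is_case"].nunique() < 2:
                raise ValueError(
                    "need both case and base moments in each group level")
        self.sample = sample
        self.include_interaction = include_interaction

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> CaseBaseResults:
        m = self.sample.moments
        names = ["intercept", "group", "day"]
        cols = [np.ones(len(m)), m["group"].to_numpy(float), m["day"].to_numpy(float)]
        if self.include_interaction:
            names.append("group_x_day")
            cols.append(cols[1] * cols[2])
        X = np.column_stack(cols)
        glm = sm.GLM(m["is_case"].to_numpy(float), X, family=sm.families.Binomial())
        res = glm.fit(tol=tol, maxiter=maxiter)
        if not res.converged:
            raise RuntimeError("case-base logistic fit did not converge")
        if np.max(np.abs(res.params[[1]])) > 15:
            raise RuntimeError("separation suspected in case-base fit")
        idx = pd.Index(names)
        return CaseBaseResults(
            params=pd.Series(res.params, index=idx),
            bse=pd.Series(res.bse, index=idx),
            cov=pd.DataFrame(res.cov_params(), index=idx, columns=idx),
            offset=self.sample.offset,
            converged=True,
            n_cases=self.sample.n_cases,
            include_interaction=self.include_interaction,
        )


def fit_casebase(sample: PersonMomentSample, include_interaction: bool = True,
                 **kwargs) -> CaseBaseResults:
    """Functional wrapper around :class:`CaseBaseHazardModel`."""
    return CaseBaseHazardModel(sample, include_interaction).fit(**kwargs)


def time_varying_hr(fit: CaseBaseResults, day: float) -> dict:
    """Active-vs-placebo hazard ratio at ``day`` with delta-method 95% CI."""
    if day < 0:
        raise ValueError("day must be nonnegative")
    names = ["group"] + (["group_x_day"] if fit.include_interaction else [])
    grad = pd.Series(0.0, index=fit.params.index)
    grad["group"] = 1.0
    if fit.include_interaction:
        grad["group_x_day"] = day
    log_hr = float(grad @ fit.params)
    se = float(np.sqrt(grad @ fit.cov @ grad))
    z = 1.959963984540054
    return {
        "day": day,
        "hr": float(np.exp(log_hr)),
        "lower": float(np.exp(log_hr - z * se)),
        "upper": float(np.exp(log_hr + z * se)),
        "log_hr": log_hr,
        "se": se,
    }


def pool_interactions(fits: list[CaseBaseResults], moderator=None):
    """Random-effects pooling of per-trial group x time interactions.

    With ``moderator`` labels (e.g. oral vs LAI) additionally returns the
    fixed-effect contrast of the interaction between moderator levels.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs at least two fits")
    est = [f.beta_interaction for f in fits]
    se = [float(f.bse["group_x_day"]) for f in fits]
    pooled = dl_random_effects(est, se)
    if moderator is None:
        return pooled
    return pooled, meta_moderator(est, se, moderator)
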