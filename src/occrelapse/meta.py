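"""Random-effects pooling and moderator tests for per-trial coefficients.

Pooling uses the DerSimonian-Laird moment estimator: with fixed-effect
weights w_i = 1/se_i^2 and Q = sum w_i (b_i - b_FE)^2,

    tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))

after which random-effects weights 1/(se_i^2 + tau^2) give the pooled
estimate and its standard error.  Moderator (e.g. formulation) tests are
fixed-effect inverse-variance meta-regressions on level indicators with a
Wald chi-square on the moderator block and all pairwise level contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "ModeratorResult", "dl_random_effects", "meta_moderator"]


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects summary of k per-trial estimates."""

    pooled_estimate: float
    pooled_se: float
    tau_squared: float
    z_value: float
    p_value: float
    k: int
    per_trial_weights: np.ndarray = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return (self.pooled_estimate - z * self.pooled_se,
                self.pooled_estimate + z * self.pooled_se)

    def to_dict(self) -> dict:
        lo, hi = self.conf_int()
        return {
            "pooled_estimate": self.pooled_estimate,
            "pooled_se": self.pooled_se,
            "tau_squared": self.tau_squared,
            "z_value": self.z_value,
            "p_value": self.p_value,
            "k": self.k,
            "ci95": [lo, hi],
            "per_trial_weights": self.per_trial_weights.tolist(),
        }


def dl_random_effects(estimates, ses) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-trial estimates."""
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.shape != se.shape or b.ndim != 1 or b.size < 1:
        raise ValueError("estimates and ses must be equal-length 1-d arrays, k >= 1")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    k = b.size
    w = 1.0 / se**2
    b_fe = np.sum(w * b) / np.sum(w)
    q = np.sum(w * (b - b_fe) ** 2)
    if k == 1:
        tau2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
    w_re = 1.0 / (se**2 + tau2)
    pooled = np.sum(w_re * b) / np.sum(w_re)
    pooled_se = np.sqrt(1.0 / np.sum(w_re))
    z = pooled / pooled_se
    return MetaResult(
        pooled_estimate=float(pooled),
        pooled_se=float(pooled_se),
        tau_squared=float(tau2),
        z_value=float(z),
        p_value=float(2 * stats.norm.sf(abs(z))),
        k=k,
        per_trial_weights=w_re / np.sum(w_re),
    )


@dataclass(frozen=True)
class ModeratorResult:
    """Wald-type moderator test across trial-level estimates."""

    q_statistic: float
    df: int
    p_value: float
    level_estimates: dict
    level_ses: dict
    pairwise: list  # dicts with levels, difference, se, z, p

    def to_dict(self) -> dict:
        return {
            "q_statistic": self.q_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "level_estimates": self.level_estimates,
            "level_ses": self.level_ses,
            "pairwise": self.pairwise,
        }


def meta_moderator(estimates, ses, moderator) -> ModeratorResult:
    """Fixed-effect inverse-variance meta-regression on moderator levels.

    Equivalent to a weighted least-squares fit of the per-trial estimates on
    level indicators with known sampling variances (scale fixed at 1); the
    Wald chi-square tests equality of all level means on (levels - 1) df.
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    labels = np.asarray(moderator)
    if not (b.shape == se.shape == labels.shape) or b.ndim != 1:
        raise ValueError("estimates, ses and moderator must be equal-length 1-d")
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    levels = sorted(set(labels.tolist()))
    if len(levels) < 2:
        raise ValueError("moderator needs at least two levels with >= 1 trial each")
    w = 1.0 / se**2
    # per-level inverse-variance-weighted means (cell-means parameterisation)
    mu, var = {}, {}
    for lev in levels:
        m = labels == lev
        mu[lev] = float(np.sum(w[m] * b[m]) / np.sum(w[m]))
        var[lev] = float(1.0 / np.sum(w[m]))
    means = np.array([mu[lev] for lev in levels])
    variances = np.array([var[lev] for lev in levels])
    # Wald test of equal level means: weighted about their common estimate
    wl = 1.0 / variances
    grand = np.sum(wl * means) / np.sum(wl)
    q = float(np.sum(wl * (means - grand) ** 2))
    df = len(levels) - 1
    pairwise = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            diff = means[i] - means[j]
            sed = np.sqrt(variances[i] + variances[j])
            z = diff / sed
            pairwise.append(
                {
                    "levels": [levels[i], levels[j]],
                    "difference": float(diff),
                    "se": float(sed),
                    "z": float(z),
                    "p": float(2 * stats.norm.sf(abs(z))),
                }
            )
    return ModeratorResult(
        q_statistic=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        level_estimates={lev: mu[lev] for lev in levels},
        level_ses={lev: float(np.sqrt(var[lev])) for lev in levels},
        pairwise=pairwise,
    )
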