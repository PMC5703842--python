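"""Optimal-stopping analysis of the balloon task and behavioral summaries.

With pop times tau ~ N(mu, sigma^2) and value R = alpha*t, the expected
reward of stopping at time t is

    E[R | t] = alpha * t * (1 - Phi((t - mu) / sigma)),

the product of linear value growth and the survival probability of the
balloon. The optimal stop time maximizes this product; it depends only on
(mu, sigma), not on the reward slope alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bartstop.containers import validate_trials


@dataclass
class PopTimeDistribution:
    """Gaussian pop-time law for one risk level."""

    mean_s: float
    sd_s: float

    def __post_init__(self) -> None:
        if self.sd_s <= 0:
            raise ValueError("sd_s must be positive")


@dataclass
class RewardModel:
    """Linear value growth: R = rate * t points after t seconds."""

    rate_points_per_s: float = 30.0

    def __post_init__(self) -> None:
        if self.rate_points_per_s <= 0:
            raise ValueError("reward rate must be positive")


def expected_reward(
    t: float | np.ndarray, dist: PopTimeDistribution, reward: RewardModel
) -> float | np.ndarray:
    """Expected banked points for stopping at elapsed time ``t``.

    ``rate * t * (1 - Phi((t - mu)/sigma))``; vectorized over ``t``.
    """
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("elapsed time must be non-negative")
    z = (t_arr - dist.mean_s) / dist.sd_s
    out = reward.rate_points_per_s * t_arr * stats.norm.sf(z)
    return float(out) if np.isscalar(t) else out


def optimal_stop_time(
    dist: PopTimeDistribution,
    reward: RewardModel | None = None,
    grid_ms: float = 1.0,
) -> float:
    """Numerically maximize expected reward over (0, mu + 6 sigma].

    Dense grid search at ``grid_ms`` resolution followed by golden-section
    refinement within the bracketing grid cell. The objective is cheap and
    unimodal for mu > 0, so this is robust to optimizer tolerances. The
    result is invariant to the reward rate (a positive scale factor).
    """
    if reward is None:
        reward = RewardModel()
    hi = dist.mean_s + 6 * dist.sd_s
    grid = np.arange(grid_ms / 1000.0, hi + grid_ms / 1000.0, grid_ms / 1000.0)
    vals = expected_reward(grid, dist, reward)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    up = grid[min(k + 1, len(grid) - 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -expected_reward(float(t), dist, reward),
        bounds=(lo, up),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def behavioral_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition behavioral summary.

    One row per (trial type, risk level): mean inflate time (stop time on
    non-popped trials), fraction popped, and mean points. Conditions with
    no trials contributing a statistic report NaN rather than zero.
    """
    validate_trials(trials)
    rows = []
    for (ttype, risk), grp in trials.groupby(["type", "risk"], sort=True):
        stopped = grp["t_stop_s"].dropna()
        n_popped = int((grp["outcome"] == "popped").sum())
        rows.append(
            {
                "type": ttype,
                "risk": risk,
                "n_trials": len(grp),
                "mean_inflate_s": float(stopped.mean()) if len(stopped) else np.nan,
                "frac_popped": n_popped / len(grp) if len(grp) else np.nan,
                "mean_points": float(grp["points"].mean())
                if grp["points"].notna().any()
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
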