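"""Regularized Poisson GLM of single-unit firing during the balloon task.

Spike counts N in Delta-t = 50 ms bins are modeled as Poisson with rate f,

    log f = beta0 + beta . X + gamma * log(t - t0 + 1),

where X holds task-epoch indicators (trial period, inflation, outcome),
outcome type (no-points vs the banked reference), and trial type (risk
color or control vs the inter-trial baseline reference), and the last term
is a power-law gain in elapsed trial time: f = alpha * (t - t0 + 1)**gamma.
The model is fit with elastic-net regularization, 10-fold cross-validation
over a lambda path and a mixing-parameter grid, and the one-standard-error
rule for parsimony. Regressors are deliberately not orthogonalized;
multicollinearity is handled by the regularization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bartstop._glmnet import PoissonElasticNetPath, cv_poisson_path
from bartstop.containers import SpikeData, trial_end_s, validate_trials

RATE_MIN_HZ, RATE_MAX_HZ = 5.0, 100.0
#: documented floor for the baseline rate when a unit has no spikes at all
RATE_FLOOR_HZ = 1e-3


def filter_units(spikes: SpikeData, session_duration_s: float | None = None) -> SpikeData:
    """Keep units with session-average rate in [5, 100] spikes/s (inclusive).

    Units outside this range are rejected as physiologically implausible
    for the target nucleus (or as likely sorting artifacts).
    """
    duration = session_duration_s or spikes.session_duration_s
    if duration <= 0:
        raise ValueError("session duration must be positive")
    kept = {
        u: t
        for u, t in spikes.timestamps.items()
        if RATE_MIN_HZ <= len(t) / duration <= RATE_MAX_HZ
    }
    return SpikeData(timestamps=kept, session_duration_s=duration)


@dataclass
class GlmDesign:
    """Bin-aligned regressor matrix for the spiking GLM.

    ``matrix`` is (n_bins, p) with named ``columns``; rows align one-to-one
    with 50 ms bins spanning the session. Indicator columns are {0, 1};
    ``log_elapsed`` is log(t - t0 + 1) at the bin center within trials and
    0 outside them.
    """

    matrix: np.ndarray
    columns: list[str]
    edges: np.ndarray
    bin_s: float

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]


def build_design(
    trials: pd.DataFrame,
    bin_s: float = 0.05,
    outcome_dur_s: float = 1.0,
    duration_s: float | None = None,
) -> GlmDesign:
    """Construct the GLM design matrix from a trial table.

    Epochs per trial (half-open intervals on the session clock):
    inflation = [start, end), outcome = [end, end + outcome_dur_s), trial =
    their union; ``end`` is the stop (or pop) time. Categorical regressors
    are expanded to indicators against documented reference levels:
    inter-trial baseline for trial type and banked reward for outcome type.
    ``control`` covers forced and gray trials; free trials get their risk
    color's indicator. The elapsed-time column is log(t - t0 + 1) at bin
    centers within the trial period.
    """
    validate_trials(trials)
    starts = trials["t_start_s"].to_numpy(float)
    ends = trial_end_s(trials)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("overlapping trials")
    if duration_s is None:
        duration_s = float(ends.max() + outcome_dur_s + 1.0)
    n_bins = int(np.ceil(duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    t = (edges[:-1] + edges[1:]) / 2

    free_risks = sorted(trials.loc[trials["type"] == "free", "risk"].unique())
    columns = (
        ["trial", "inflation", "outcome", "outcome_nopoints"]
        + [f"risk_{r}" for r in free_risks]
        + ["control", "log_elapsed"]
    )
    X = np.zeros((n_bins, len(columns)))
    col = {c: i for i, c in enumerate(columns)}

    for row, start, end in zip(trials.itertuples(index=False), starts, ends):
        infl = (t >= start) & (t < end)
        outc = (t >= end) & (t < end + outcome_dur_s)
        trial = infl | outc
        X[trial, col["trial"]] = 1
        X[infl, col["inflation"]] = 1
        X[outc, col["outcome"]] = 1
        if row.outcome in ("popped", "no_reward"):
            X[outc, col["outcome_nopoints"]] = 1
        if row.type == "free":
            X[trial, col[f"risk_{row.risk}"]] = 1
        else:
            X[trial, col["control"]] = 1
        X[trial, col["log_elapsed"]] = np.log(t[trial] - start + 1.0)
    return GlmDesign(matrix=X, columns=columns, edges=edges, bin_s=bin_s)


@dataclass
class GlmFit:
    """Fitted spiking GLM.

    ``beta0`` is the intercept with the bin width absorbed as an offset, so
    the baseline firing rate is ``f0 = exp(beta0)`` in spikes/s. ``gamma``
    is the coefficient on the log-elapsed-time column (the power-law
    exponent). ``cv_table`` records mean/SE cross-validated deviance along
    the path for the chosen mixing value.
    """

    beta0: float
    beta: dict[str, float]
    lambda_: float
    mixing: float
    rule: str
    bin_s: float
    cv_table: pd.DataFrame | None = None

    @property
    def gamma(self) -> float:
        return self.beta.get("log_elapsed", 0.0)

    @property
    def baseline_rate_hz(self) -> float:
        return float(np.exp(self.beta0))


def fit_poisson_glm(
    design: GlmDesign,
    counts: np.ndarray,
    folds: int = 10,
    mixing_grid: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    rule: str = "1SE",
    seed: int = 0,
    n_lambda: int = 100,
) -> GlmFit:
    """Fit the elastic-net Poisson GLM with cross-validated (lambda, mixing).

    For every mixing value in ``mixing_grid`` a lambda path is fit and
    scored by ``folds``-fold cross-validated Poisson deviance on seeded
    random partitions of bins. The mixing value with the best minimum CV
    deviance is chosen; within it, ``rule`` selects lambda: ``"1SE"`` takes
    the largest lambda within one standard error of the best deviance (the
    most parsimonious statistically indistinguishable model), ``"min"`` the
    best-performing lambda, and ``"none"`` the plain unpenalized MLE (for
    comparison fits; ill-posed on exactly collinear designs). The intercept is
    never penalized; the log bin width enters as an offset so rates are in
    spikes/s.
    """
    counts = np.asarray(counts, float).ravel()
    if len(counts) != design.n_bins:
        raise ValueError("counts and design are not row-aligned")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if rule not in ("1SE", "min", "none"):
        raise ValueError("rule must be '1SE', 'min', or 'none'")
    offset = np.log(design.bin_s)
    rng = np.random.default_rng(seed)
    results = []
    for a in mixing_grid:
        fold_rng = np.random.default_rng(rng.integers(2**31 - 1))
        results.append(
            (
                a,
                cv_poisson_path(
                    design.matrix,
                    counts,
                    offset,
                    alpha=a,
                    n_folds=folds,
                    rng=fold_rng,
                    n_lambda=n_lambda,
                ),
            )
        )
    best_alpha, best = min(results, key=lambda r: r[1]["mean_dev"][r[1]["idx_min"]])
    path: PoissonElasticNetPath = best["path"]
    if rule == "none":
        idx = len(path.lambdas) - 1
        b0, b = path.unpenalized()
    else:
        idx = {"1SE": best["idx_1se"], "min": best["idx_min"]}[rule]
        b0, b = path.coefs(idx)
    cv_table = pd.DataFrame(
        {
            "lambda": path.lambdas,
            "mean_deviance": best["mean_dev"],
            "se_deviance": best["se_dev"],
        }
    )
    return GlmFit(
        beta0=float(b0),
        beta=dict(zip(design.columns, b)),
        lambda_=float(path.lambdas[idx]),
        mixing=float(best_alpha),
        rule=rule,
        bin_s=design.bin_s,
        cv_table=cv_table,
    )


def effect_sizes(fit: GlmFit, representative_elapsed_s: float = 5.0) -> pd.DataFrame:
    """Per-regressor effect sizes as percent change from baseline firing.

    Binary/categorical effects are ``(exp(beta) - 1) * 100``; the
    elapsed-time effect is the power-law gain evaluated at a representative
    elapsed time, ``((t + 1)**gamma - 1) * 100``. ``present`` flags
    coefficients the regularization did not shrink to exactly zero.
    """
    rows = []
    for name, b in fit.beta.items():
        if name == "log_elapsed":
            pct = ((representative_elapsed_s + 1.0) ** b - 1.0) * 100.0
        else:
            pct = (np.exp(b) - 1.0) * 100.0
        rows.append(
            {"regressor": name, "coef": b, "percent_change": pct, "present": b != 0.0}
        )
    return pd.DataFrame(rows)


def shuffle_control(
    design: GlmDesign,
    counts: np.ndarray,
    seed: int = 0,
    reps: int = 10,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit after destroying temporal structure by shuffling bin order.

    Each repetition permutes the spike counts across bins (removing any
    temporal correlation the regressors could explain), refits the
    parsimonious model, and records which regressors survive with nonzero
    coefficients. On well-behaved data the expectation is zero false
    positives. Returns one row per (rep, regressor) with the nonzero flag.
    """
    counts = np.asarray(counts, float).ravel()
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("rule", "1SE")
    rows = []
    for rep in range(reps):
        perm = rng.permutation(len(counts))
        fit = fit_poisson_glm(
            design, counts[perm], seed=int(rng.integers(2**31 - 1)), **fit_kwargs
        )
        for name, b in fit.beta.items():
            rows.append({"rep": rep, "regressor": name, "nonzero": b != 0.0})
    return pd.DataFrame(rows)
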