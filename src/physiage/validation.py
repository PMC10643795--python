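"""Statistical validation of the clock.

Covers the four checks run against a fitted clock: the alive-vs-deceased
deltaAge contrast on held-out data (and the analogous PhysiAge contrast in
the 85+ group scored at a default age of 85), leave-one-parameter-out
ablation with the accuracy-versus-mortality-signal tradeoff, robustness of
the test RMSE to the random train/test split, and the Pearson
cross-correlation matrix of the clock's inputs.

The two-sample t test defaults to Welch (unequal variances); a
pooled-variance option is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clock import (
    MODEL_PREDICTORS,
    FitResult,
    build_normalization,
    fit_model,
    score_table,
    split_train_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AblationResult",
    "MortalityContrast",
    "SplitRobustnessResult",
    "ablation",
    "cross_correlation",
    "mortality_contrast",
    "rmse",
    "score_85plus",
    "split_robustness",
]


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-squared error between two equal-length vectors (years)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


@dataclass
class MortalityContrast:
    """Alive-vs-deceased two-sample contrast on a scored table."""

    n_alive: int
    n_deceased: int
    mean_alive: float
    mean_deceased: float
    median_alive: float
    median_deceased: float
    t_statistic: float
    p_value: float
    variant: str = "welch"


def _contrast(values_alive, values_deceased, equal_var: bool) -> tuple[float, float]:
    pooled = np.concatenate([values_alive, values_deceased])
    if np.ptp(pooled) == 0:  # degenerate: no variance anywhere
        return 0.0, 1.0
    result = stats.ttest_ind(values_deceased, values_alive, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)


def mortality_contrast(
    scored_test: pd.DataFrame,
    value_column: str = "delta_age",
    equal_var: bool = False,
) -> MortalityContrast:
    """Two-tailed two-sample t test on deltaAge, alive vs deceased.

    Welch's unequal-variance form by default; pass ``equal_var=True`` for
    the pooled-variance (classical Student) form.
    """
    known = scored_test[scored_test["vital_status"].isin(["alive", "deceased"])]
    alive = known.loc[known["vital_status"] == "alive", value_column].to_numpy(float)
    dead = known.loc[known["vital_status"] == "deceased", value_column].to_numpy(float)
    for name, group in (("alive", alive), ("deceased", dead)):
        if len(group) < 2:
            raise ValueError(f"group too small: {name!r} has {len(group)} member(s)")
    t, p = _contrast(alive, dead, equal_var)
    return MortalityContrast(
        n_alive=len(alive),
        n_deceased=len(dead),
        mean_alive=float(alive.mean()),
        mean_deceased=float(dead.mean()),
        median_alive=float(np.median(alive)),
        median_deceased=float(np.median(dead)),
        t_statistic=t,
        p_value=p,
        variant="pooled" if equal_var else "welch",
    )


def score_85plus(model, nf, table_85plus: pd.DataFrame, equal_var: bool = False):
    """Score the held 85+ table at a default age of 85 and contrast PhysiAge.

    The contrast is on the PhysiAge score itself (not deltaAge): with all
    ages fixed at 85, deltaAge differs from PhysiAge only by a constant.
    """
    scored = table_85plus.copy()
    scored["age"] = 85
    scored["is_85plus"] = True
    scored = score_table(model, nf, scored)
    return mortality_contrast(scored, value_column="physiage", equal_var=equal_var)


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------


@dataclass
class AblationResult:
    """One leave-one-parameter-out variant of the clock."""

    omitted: str  # "all parameters" for the full model
    fit: FitResult
    test_rmse: float
    mortality_p: float


def ablation(
    train: pd.DataFrame,
    test: pd.DataFrame,
    predictors: Sequence[str] = MODEL_PREDICTORS,
    response: str = "phenoage",
    equal_var: bool = False,
) -> list[AblationResult]:
    """Refit the clock with each predictor omitted once, on a fixed split.

    Returns five rows: the all-parameters model first, then one per
    omission. Every variant is refit, gets its own rebuilt normalization
    table, and is evaluated on the same held-out test table (RMSE of
    PhysiAge against calendar age, and the alive/deceased deltaAge
    contrast's p value).
    """
    variants: list[tuple[str, tuple[str, ...]]] = [("all parameters", tuple(predictors))]
    variants += [
        (omit, tuple(p for p in predictors if p != omit)) for omit in predictors
    ]
    results = []
    for label, kept in variants:
        fit = fit_model(train, predictors=kept, response=response)
        nf = build_normalization(train, fit.model)
        scored = score_table(fit.model, nf, test)
        results.append(
            AblationResult(
                omitted=label,
                fit=fit,
                test_rmse=rmse(scored["physiage"], scored["age"]),
                mortality_p=mortality_contrast(scored, equal_var=equal_var).p_value,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Split robustness
# ---------------------------------------------------------------------------


@dataclass
class SplitRobustnessResult:
    """Test RMSE of the full pipeline under different random data splits."""

    seeds: list[int]
    rmses: list[float]

    @property
    def min(self) -> float:
        return float(np.min(self.rmses))

    @property
    def median(self) -> float:
        return float(np.median(self.rmses))

    @property
    def max(self) -> float:
        return float(np.max(self.rmses))


def split_robustness(
    prepared: pd.DataFrame,
    seeds: Sequence[int],
    train_fraction: float = 0.8,
    predictors: Sequence[str] = MODEL_PREDICTORS,
    response: str = "phenoage",
) -> SplitRobustnessResult:
    """Rerun split -> fit -> normalization -> test RMSE for each seed."""
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds to assess split robustness")
    rmses = []
    for seed in seeds:
        train, test = split_train_test(prepared, train_fraction, seed=seed)
        fit = fit_model(train, predictors=predictors, response=response)
        nf = build_normalization(train, fit.model)
        scored = score_table(fit.model, nf, test)
        rmses.append(rmse(scored["physiage"], scored["age"]))
    return SplitRobustnessResult(seeds=list(seeds), rmses=rmses)


# ---------------------------------------------------------------------------
# Cross-correlation of inputs
# ---------------------------------------------------------------------------

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, mark in _STAR_THRESHOLDS:
        if p < cut:
            return mark
    return ""


def cross_correlation(
    table: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with p values and significance stars.

    Returns ``(r, p, stars)`` DataFrames indexed by variable. Zero-variance
    columns get NaN off-diagonal entries and are logged as undefined.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 complete rows")
    cols = list(variables)
    data = table[cols].to_numpy(dtype=float)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = [c for i, c in enumerate(cols) if np.std(data[:, i]) == 0]
    if degenerate:
        logger.warning("zero-variance column(s), correlations undefined: %s", degenerate)
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in degenerate or cols[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(data[:, i], data[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    stars_df = p_df.map(lambda v: "" if np.isnan(v) else _stars(v))
    np.fill_diagonal(stars_df.values, "")
    return r_df, p_df, stars_df
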