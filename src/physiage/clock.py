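"""The PhysiAge clock.

PhysiAge predicts phenotypic age from four easily tracked inputs — sex,
fasting blood glucose (mmol/L), average daily step count and systolic blood
pressure (mmHg) — with an ordinary least-squares fit, then re-anchors the
raw prediction to the age axis with a median-per-age normalization factor:

    raw      = b0 + b_sex*Sex + b_gluc*Gluc + b_steps*Steps + b_sbp*SysBP
    PhysiAge = raw / NF(age) * age
    deltaAge = PhysiAge - age

NF(a) is the median raw prediction among training participants of integer
calendar age a, which makes the median deltaAge exactly zero at every
populated training age. The published constants of the model are available
as :data:`PUBLISHED_MODEL`.

Sex is coded 1 for men, 0 for women. Participants recorded as 85+ (whose
exact age is unknown) are excluded from fitting; they are scored with a
default age of 85 and the normalization factor clamped to the highest
tabulated age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_PREDICTORS",
    "PUBLISHED_MODEL",
    "NormalizationTable",
    "PhysiAgeModel",
    "QCReport",
    "SingularModelError",
    "build_normalization",
    "fit_model",
    "load_model",
    "physiage_score",
    "qc_filter",
    "raw_predict",
    "remove_step_outliers",
    "save_model",
    "score_table",
    "split_train_test",
    "whatif_sweep",
]

#: Canonical predictor columns, in published order.
MODEL_PREDICTORS = ("sex", "glucose", "avg_daily_steps", "systolic_bp")

#: Conversion divisor for glucose reported in mg/dL.
MG_PER_DL_PER_MMOL_PER_L = 18.016


class SingularModelError(ValueError):
    """The design matrix is rank deficient; a coefficient is inestimable."""


@dataclass(frozen=True)
class PhysiAgeModel:
    """Intercept plus one coefficient per predictor of the linear clock."""

    intercept: float
    coefs: Mapping[str, float]

    def __post_init__(self) -> None:
        values = [self.intercept, *self.coefs.values()]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("model coefficients must all be finite")

    # Named accessors for the canonical predictor set.
    @property
    def coef_sex(self) -> float:
        return self.coefs["sex"]

    @property
    def coef_glucose(self) -> float:
        return self.coefs["glucose"]

    @property
    def coef_steps(self) -> float:
        return self.coefs["avg_daily_steps"]

    @property
    def coef_sysbp(self) -> float:
        return self.coefs["systolic_bp"]

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        """Vectorized affine evaluation over a table's predictor columns."""
        out = np.full(len(table), self.intercept, dtype=float)
        for name, coef in self.coefs.items():
            out += coef * table[name].to_numpy(dtype=float)
        return out


#: The published constants of the final clock.
PUBLISHED_MODEL = PhysiAgeModel(
    intercept=-18.5,
    coefs={
        "sex": 1.972,
        "glucose": 3.348,
        "avg_daily_steps": -0.0004715,
        "systolic_bp": 0.3988,
    },
)


def raw_predict(
    model: PhysiAgeModel,
    sex: int,
    glucose: float,
    steps: float,
    systolic_bp: float,
) -> float:
    """Exact affine evaluation of the clock's linear predictor (years).

    Units: glucose mmol/L, steps per day, systolic BP mmHg; sex in {0, 1}.
    """
    if sex not in (0, 1):
        raise ValueError(f"sex must be 0 (female) or 1 (male), got {sex!r}")
    if glucose <= 0:
        raise ValueError("glucose must be positive (mmol/L)")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    return (
        model.intercept
        + model.coefs.get("sex", 0.0) * sex
        + model.coefs.get("glucose", 0.0) * glucose
        + model.coefs.get("avg_daily_steps", 0.0) * steps
        + model.coefs.get("systolic_bp", 0.0) * systolic_bp
    )


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-reason exclusion tally from :func:`qc_filter`."""

    n_input: int
    n_zero_or_missing: int
    n_age_out_of_range: int
    n_85plus: int
    n_retained: int

    @property
    def n_excluded(self) -> int:
        return self.n_zero_or_missing + self.n_age_out_of_range + self.n_85plus


def qc_filter(
    raw_table: pd.DataFrame,
    required_columns: Sequence[str] = ("age", "sex", *MODEL_PREDICTORS[1:]),
    age_range: tuple[int, int] = (20, 84),
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Apply the completeness and age filters.

    Rows with a zero or missing entry in any required column are excluded;
    ages outside ``age_range`` are excluded, except that rows flagged 85+
    (``is_85plus`` or age >= 85) are routed to a separate held table for
    later scoring rather than silently dropped. Returns
    ``(filtered, held_85plus, report)``.
    """
    missing_cols = [c for c in required_columns if c not in raw_table.columns]
    if missing_cols:
        raise KeyError(f"required column(s) absent: {missing_cols}")
    table = raw_table.copy()
    values = table[list(required_columns)]
    bad = values.isna().any(axis=1) | (values == 0).any(axis=1)
    # sex == 0 is a valid code (female), not a missing entry
    if "sex" in required_columns:
        bad = (
            values.drop(columns=["sex"]).isna().any(axis=1)
            | (values.drop(columns=["sex"]) == 0).any(axis=1)
            | values["sex"].isna()
        )
    table = table[~bad]

    if "is_85plus" in table.columns:
        held_mask = table["is_85plus"].astype(bool) | (table["age"] >= 85)
    else:
        held_mask = table["age"] >= 85
    held = table[held_mask].copy()
    table = table[~held_mask]

    lo, hi = age_range
    in_range = (table["age"] >= lo) & (table["age"] <= hi)
    out_of_range = int((~in_range).sum())
    table = table[in_range]

    report = QCReport(
        n_input=len(raw_table),
        n_zero_or_missing=int(bad.sum()),
        n_age_out_of_range=out_of_range,
        n_85plus=len(held),
        n_retained=len(table),
    )
    logger.info(
        "qc: %d in, %d zero/missing, %d out-of-range, %d held 85+, %d retained",
        report.n_input,
        report.n_zero_or_missing,
        report.n_age_out_of_range,
        report.n_85plus,
        report.n_retained,
    )
    return table.reset_index(drop=True), held.reset_index(drop=True), report


def remove_step_outliers(
    table: pd.DataFrame, k: float = 1.5, column: str = "avg_daily_steps"
) -> pd.DataFrame:
    """Drop rows whose step count is a box-and-whisker outlier.

    Fences are [Q1 - k*IQR, Q3 + k*IQR] with quartiles over the whole
    population. Fewer than 4 rows: no-op with a warning.
    """
    if column not in table.columns:
        raise KeyError(f"column {column!r} absent")
    if k <= 0:
        raise ValueError("fence multiplier k must be > 0")
    if len(table) < 4:
        logger.warning("fewer than 4 rows; step-outlier removal skipped")
        return table.copy()
    steps = table[column].to_numpy(dtype=float)
    q1, q3 = np.percentile(steps, [25, 75])
    iqr = q3 - q1
    keep = (steps >= q1 - k * iqr) & (steps <= q3 + k * iqr)
    removed = int((~keep).sum())
    if removed:
        logger.info("step-outlier removal: %d row(s) outside Tukey fences", removed)
    return table[keep].reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sex-stratified random split into disjoint train and test tables.

    Within each sex stratum the training count is round-half-up of
    fraction * stratum size; the partition is deterministic under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    table = table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    for sex_value, stratum in table.groupby("sex"):
        n = len(stratum)
        if n == 0:
            logger.info("sex stratum %s is empty", sex_value)
            continue
        n_train = int(math.floor(train_fraction * n + 0.5))
        perm = rng.permutation(n)
        train_idx.append(stratum.index.to_numpy()[perm[:n_train]])
    chosen = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    mask = table.index.isin(chosen)
    return (
        table[mask].reset_index(drop=True),
        table[~mask].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Fitting and normalization
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """An OLS fit of the clock with its diagnostics."""

    model: PhysiAgeModel
    pvalues: dict[str, float]
    stderr: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    n_obs: int
    rsquared: float


def fit_model(
    train: pd.DataFrame,
    predictors: Sequence[str] = MODEL_PREDICTORS,
    response: str = "phenoage",
) -> FitResult:
    """Ordinary least-squares fit of the clock on a training table."""
    if len(train) < len(predictors) + 1:
        raise ValueError("need at least 5 non-collinear rows to fit")
    X = train[list(predictors)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        constant = [p for p in predictors if train[p].nunique() <= 1]
        detail = f" (constant column(s): {constant})" if constant else ""
        raise SingularModelError(f"design matrix is rank deficient{detail}")
    fit = sm.OLS(train[response].to_numpy(dtype=float), design).fit()
    names = ["intercept", *predictors]
    ci = fit.conf_int()
    return FitResult(
        model=PhysiAgeModel(
            intercept=float(fit.params[0]),
            coefs={p: float(fit.params[i + 1]) for i, p in enumerate(predictors)},
        ),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        stderr=dict(zip(names, map(float, fit.bse))),
        conf_int={n: (float(ci[i, 0]), float(ci[i, 1])) for i, n in enumerate(names)},
        n_obs=int(fit.nobs),
        rsquared=float(fit.rsquared),
    )


@dataclass
class NormalizationTable:
    """Integer calendar age -> NF_Age divisor.

    ``interpolated`` flags ages filled by linear interpolation between the
    nearest populated ages (endpoints take the nearest populated value).
    Ages above the tabulated maximum are served the maximum age's value
    (clamping, logged) so 85+ participants can be scored.
    """

    values: dict[int, float]
    interpolated: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("normalization table is empty")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("normalization factors must all be > 0")

    @property
    def ages(self) -> list[int]:
        return sorted(self.values)

    def nf(self, age: int) -> float:
        """NF for ``age``, clamping above the table's maximum."""
        age = int(age)
        if age in self.values:
            return self.values[age]
        max_age = max(self.values)
        if age > max_age:
            logger.info("NF clamped: age %d served NF(%d)", age, max_age)
            return self.values[max_age]
        raise KeyError(f"age {age} below the tabulated range and unclampable")

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "age": self.ages,
                "nf": [self.values[a] for a in self.ages],
                "interpolated": [a in self.interpolated for a in self.ages],
            }
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormalizationTable":
        frame = pd.read_csv(path)
        if not {"age", "nf"} <= set(frame.columns):
            raise ValueError(f"NF table {path} must have columns age, nf")
        interp = (
            frame.loc[frame["interpolated"].astype(bool), "age"].astype(int)
            if "interpolated" in frame.columns
            else []
        )
        return cls(
            values={int(a): float(v) for a, v in zip(frame["age"], frame["nf"])},
            interpolated=frozenset(int(a) for a in interp),
        )


def build_normalization(train: pd.DataFrame, model: PhysiAgeModel) -> NormalizationTable:
    """Median raw prediction per integer training age, gaps interpolated."""
    if len(train) == 0:
        raise ValueError("cannot build a normalization table from an empty table")
    raw = model.predict_frame(train)
    ages = train["age"].to_numpy(dtype=int)
    medians = {
        int(a): float(np.median(raw[ages == a])) for a in np.unique(ages)
    }
    lo, hi = min(medians), max(medians)
    populated = sorted(medians)
    full = {}
    filled = set()
    for a in range(lo, hi + 1):
        if a in medians:
            full[a] = medians[a]
        else:
            full[a] = float(
                np.interp(a, populated, [medians[p] for p in populated])
            )
            filled.add(a)
    if filled:
        logger.info("NF table: %d age(s) filled by interpolation", len(filled))
    return NormalizationTable(values=full, interpolated=frozenset(filled))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def physiage_score(
    model: PhysiAgeModel,
    nf: NormalizationTable,
    *,
    age: int,
    sex: int,
    glucose: float,
    steps: float,
    systolic_bp: float,
    is_85plus: bool = False,
) -> dict[str, float]:
    """Score one participant: raw prediction, PhysiAge and deltaAge.

    Participants flagged 85+ are scored with a default age of 85 and the
    normalization factor clamped to the table's maximum age.
    """
    eff_age = 85 if (is_85plus or age >= 85) else int(age)
    raw = raw_predict(model, sex, glucose, steps, systolic_bp)
    factor = nf.nf(eff_age)
    score = raw / factor * eff_age
    return {
        "raw_prediction": raw,
        "physiage": score,
        "delta_age": score - eff_age,
    }


def score_table(
    model: PhysiAgeModel, nf: NormalizationTable, table: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized scoring; appends raw_prediction, physiage, delta_age."""
    out = table.copy()
    raw = model.predict_frame(out)
    if "is_85plus" in out.columns:
        flag = out["is_85plus"].astype(bool) | (out["age"] >= 85)
    else:
        flag = out["age"] >= 85
    eff_age = np.where(flag, 85, out["age"].to_numpy(dtype=int))
    factors = np.array([nf.nf(a) for a in eff_age])
    out["raw_prediction"] = raw
    out["physiage"] = raw / factors * eff_age
    out["delta_age"] = out["physiage"] - eff_age
    return out


DEFAULT_SWEEP_GRIDS = {
    "avg_daily_steps": np.arange(5000, 20001, 1000),
    "glucose": np.arange(4, 11, 1),
}


def whatif_sweep(
    profile: Mapping[str, float],
    variable: str,
    model: PhysiAgeModel,
    nf: NormalizationTable,
    grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """PhysiAge over a grid of one modifiable input, all else held fixed.

    ``profile`` supplies age, sex and the non-swept inputs. The default
    grids are 5,000-20,000 steps/day in 1,000-step increments and 4-10
    mmol/L glucose in 1-unit increments.
    """
    if variable not in DEFAULT_SWEEP_GRIDS:
        raise ValueError(f"sweep variable must be one of {list(DEFAULT_SWEEP_GRIDS)}")
    values = np.asarray(
        list(grid) if grid is not None else DEFAULT_SWEEP_GRIDS[variable], dtype=float
    )
    if values.size == 0:
        raise ValueError("sweep grid is empty")
    rows = []
    for v in values:
        inputs = dict(profile)
        inputs[variable] = float(v)
        scored = physiage_score(
            model,
            nf,
            age=int(inputs["age"]),
            sex=int(inputs["sex"]),
            glucose=float(inputs["glucose"]),
            steps=float(inputs["avg_daily_steps"]),
            systolic_bp=float(inputs["systolic_bp"]),
        )
        rows.append({variable: float(v), **scored})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: PhysiAgeModel, path: str | Path) -> None:
    """Key-value text file with the intercept and per-predictor coefficients."""
    payload = {"intercept": model.intercept, "coefficients": dict(model.coefs)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_model(path: str | Path) -> PhysiAgeModel:
    raw = yaml.safe_load(Path(path).read_text())
    return PhysiAgeModel(
        intercept=float(raw["intercept"]),
        coefs={k: float(v) for k, v in raw["coefficients"].items()},
    )
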