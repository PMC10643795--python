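"""Synthetic cohorts with planted, recoverable structure.

Every downstream stage of the pipeline (phenotypic-age scoring, clock
fitting, normalization, mortality contrasts, metabolite screens) is
exercised against data from this module, so each generator plants a known
signal that the stage is supposed to recover:

* ``simulate_nhanes_cohort`` draws ages uniformly over the integers 20-84
  and generates each physiological variable as a linear-in-age Gaussian,
  with the slope solved from the calibration identity

      corr = slope * sd_age / sqrt(slope^2 * sd_age^2 + sd^2)

  so the realized rank correlation with age matches a configured target.
  A latent phenotypic age is planted in each participant's biomarker panel
  through the exact inversion in :mod:`physiage.phenoage`.
* ``simulate_mortality`` assigns 10-year vital status from a Gompertz-type
  hazard increasing in latent phenotypic age (optionally also in glucose,
  to create signal that an ablated clock loses).
* ``simulate_mitohealth_cohort`` builds the 4-group validation design
  (young / trained / normal / impaired older adults) with group-level
  physiology ordered so that deltaAge ordering trained < normal < impaired
  emerges when scored.
* ``simulate_metabolome`` plants per-metabolite rank correlations to
  deltaAge with a Gaussian copula on the deltaAge ranks, then exponentiates
  to strictly positive log-normal abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .phenoage import (
    BIOMARKER_NAMES,
    PhenoAgeConfig,
    default_config,
    default_panel,
    invert_biomarker_for_phenoage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_RANGE",
    "DEFAULT_TARGET_RHOS",
    "CohortSimParams",
    "HazardParams",
    "MetabolomeSimParams",
    "MitoHealthSimParams",
    "TrendSpec",
    "invert_biomarker_for_phenoage",
    "reference_normalization",
    "simulate_metabolome",
    "simulate_mitohealth_cohort",
    "simulate_mortality",
    "simulate_nhanes_cohort",
    "solve_slope",
]

#: Retained calendar-age range (integers, inclusive).
AGE_RANGE = (20, 84)

#: Target rank correlations of each physiological variable with age.
DEFAULT_TARGET_RHOS: Mapping[str, float] = {
    "glucose": 0.400,
    "systolic_bp": 0.474,
    "diastolic_bp": -0.151,
    "resting_hr": -0.224,
    "bmi": 0.075,
    "avg_daily_steps": 0.029,
}

#: Physiological variables of the cohort table, with units.
VARIABLES = (
    "glucose",  # mmol/L
    "systolic_bp",  # mmHg
    "diastolic_bp",  # mmHg
    "resting_hr",  # bpm
    "bmi",  # kg/m^2
    "avg_daily_steps",  # steps/day
)


def _age_sd(age_range: tuple[int, int]) -> float:
    span = age_range[1] - age_range[0] + 1
    return math.sqrt((span**2 - 1) / 12.0)


def solve_slope(target_rho: float, residual_sd: float, sd_age: float) -> float:
    """Slope per year that realizes ``target_rho`` under the linear model.

    Inverts corr = slope*sd_age / sqrt(slope^2*sd_age^2 + sd^2). With a
    uniform age marginal the realized Spearman correlation tracks this
    (Pearson) calibration closely enough that targets land within sampling
    error at the default cohort size.
    """
    if not -1.0 < target_rho < 1.0:
        raise ValueError(f"infeasible calibration: |rho| must be < 1, got {target_rho}")
    if residual_sd <= 0:
        raise ValueError("residual_sd must be > 0")
    return target_rho / math.sqrt(1.0 - target_rho**2) * residual_sd / sd_age


@dataclass
class TrendSpec:
    """Linear-in-age generating law for one physiological variable."""

    intercept_at_age20: float
    slope_per_year: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


# Intercept at age 20 and residual SD per variable; slopes are solved from
# the target rank correlations.
_DEFAULT_LEVELS = {
    "glucose": (4.6, 1.1),
    "systolic_bp": (112.0, 12.0),
    "diastolic_bp": (78.0, 10.0),
    "resting_hr": (75.0, 11.0),
    "bmi": (28.0, 5.5),
    "avg_daily_steps": (9000.0, 4800.0),
}


@dataclass
class CohortSimParams:
    """Parameters of the NHANES-like cohort generator.

    ``mode`` selects how the latent phenotypic age is planted:
    ``"age_anchored"`` draws phenoage_true = age + N(0, phenoage_residual_sd)
    (matching the observed phenotypic-age/age relation), while
    ``"planted_linear"`` draws it from the published-coefficient linear
    predictor of sex, glucose, steps and systolic BP plus Gaussian noise, so
    a refit of the clock can be checked against known ground truth.
    """

    n_participants: int = 3342
    age_range: tuple[int, int] = AGE_RANGE
    male_fraction: float = 0.5
    trends: dict[str, TrendSpec] = field(default_factory=dict)
    target_rank_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_RHOS)
    )
    phenoage_residual_sd: float = 7.4
    mode: str = "age_anchored"
    planted_coefficients: tuple[float, float, float, float, float] = (
        -18.5,
        1.972,
        3.348,
        -0.0004715,
        0.3988,
    )
    planted_noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (20 <= lo <= hi <= 84):
            raise ValueError("age_range must lie within [20, 84]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be a proportion")
        if self.phenoage_residual_sd <= 0:
            raise ValueError("phenoage_residual_sd must be > 0")
        if self.mode not in ("age_anchored", "planted_linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        sd_age = _age_sd(self.age_range)
        for var in VARIABLES:
            if var not in self.trends:
                level, sd = _DEFAULT_LEVELS[var]
                rho = self.target_rank_correlations.get(var, 0.0)
                self.trends[var] = TrendSpec(level, solve_slope(rho, sd, sd_age), sd)


def _plant_panels(
    frame: pd.DataFrame, config: PhenoAgeConfig, free_biomarker: str = "rdw"
) -> pd.DataFrame:
    """Attach biomarker columns whose phenotypic age equals phenoage_true.

    The panel shares the participant's glucose and age; the free biomarker
    absorbs the target exactly (closed-form inversion), all other biomarkers
    sit at mid-normal defaults.
    """
    anchor = default_panel()
    anchor.glucose = frame["glucose"].to_numpy()
    anchor.age = frame["age"].to_numpy(dtype=float)
    panel = invert_biomarker_for_phenoage(
        frame["phenoage_true"].to_numpy(), anchor, config, free_biomarker
    )
    out = frame.copy()
    for name in BIOMARKER_NAMES:
        if name != "glucose":
            out[name] = np.broadcast_to(
                np.asarray(getattr(panel, name), dtype=float), len(frame)
            )
    return out


def simulate_nhanes_cohort(
    params: CohortSimParams | None = None,
    config: PhenoAgeConfig | None = None,
) -> pd.DataFrame:
    """Generate an NHANES-like participant table.

    Returns one row per participant with id, age, is_85plus, sex (1=male,
    0=female), the six physiological variables, the nine-biomarker panel
    consistent with the latent ``phenoage_true``, and unknown vital status.
    Reproducible under a fixed ``params.seed``.
    """
    params = params or CohortSimParams()
    config = config or default_config()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    lo, hi = params.age_range

    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": rng.integers(lo, hi + 1, size=n),
            "sex": (rng.random(n) < params.male_fraction).astype(int),
        }
    )
    frame["is_85plus"] = False
    for var in VARIABLES:
        spec = params.trends[var]
        values = (
            spec.intercept_at_age20
            + spec.slope_per_year * (frame["age"].to_numpy() - 20)
            + rng.normal(0.0, spec.residual_sd, size=n)
        )
        if var == "avg_daily_steps":
            values = np.clip(values, 0.0, None)
        elif var == "glucose":
            values = np.clip(values, 0.1, None)
        frame[var] = values

    if params.mode == "age_anchored":
        frame["phenoage_true"] = frame["age"] + rng.normal(
            0.0, params.phenoage_residual_sd, size=n
        )
    else:
        b0, b_sex, b_glu, b_steps, b_sbp = params.planted_coefficients
        frame["phenoage_true"] = (
            b0
            + b_sex * frame["sex"]
            + b_glu * frame["glucose"]
            + b_steps * frame["avg_daily_steps"]
            + b_sbp * frame["systolic_bp"]
            + rng.normal(0.0, params.planted_noise_sd, size=n)
        )

    frame = _plant_panels(frame, config)
    frame["vital_status"] = "unknown"
    frame["followup_years"] = np.nan
    return frame


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------


@dataclass
class HazardParams:
    """Gompertz-type hazard linking latent phenotypic age to 10-year death.

    h(t) = h0 * exp(b * (phenoage_true - 50) + glucose_effect * (glucose - 5.5));
    constant over the follow-up window, so the cumulative hazard is
    horizon_years * h. ``glucose_effect`` defaults to 0 and exists to build
    cohorts where glucose carries mortality signal beyond phenotypic age.
    """

    h0: float = 0.004  # baseline hazard per year at phenoage 50
    b: float = 0.08  # log-hazard slope per year of phenotypic age
    glucose_effect: float = 0.0  # log-hazard per mmol/L above 5.5
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        if self.h0 < 0:
            raise ValueError("h0 must be >= 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")


def simulate_mortality(
    cohort: pd.DataFrame, hazard: HazardParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Assign vital status at follow-up from the phenotypic-age hazard.

    Each participant dies independently with probability 1 - exp(-H) where
    H is their cumulative hazard over the follow-up horizon.
    """
    hazard = hazard or HazardParams()
    if "phenoage_true" not in cohort.columns:
        raise ValueError("cohort must carry phenoage_true to simulate mortality")
    rng = np.random.default_rng(seed)
    log_h = (
        math.log(hazard.h0) if hazard.h0 > 0 else -np.inf
    ) + hazard.b * (cohort["phenoage_true"].to_numpy() - 50.0)
    if hazard.glucose_effect != 0.0:
        log_h = log_h + hazard.glucose_effect * (cohort["glucose"].to_numpy() - 5.5)
    p_death = -np.expm1(-hazard.horizon_years * np.exp(log_h))
    deceased = rng.random(len(cohort)) < p_death
    out = cohort.copy()
    out["vital_status"] = np.where(deceased, "deceased", "alive")
    out["followup_years"] = hazard.horizon_years
    logger.info(
        "mortality simulated: %d deceased / %d alive over %.1f years",
        int(deceased.sum()),
        int((~deceased).sum()),
        hazard.horizon_years,
    )
    return out


# ---------------------------------------------------------------------------
# MitoHealth-like 4-group cohort
# ---------------------------------------------------------------------------

GROUP_ORDER = ("young", "trained", "normal", "impaired")


@dataclass
class GroupLevels:
    """Group-specific (mean, sd) for the three scored physiology variables."""

    steps: tuple[float, float]
    glucose: tuple[float, float]
    systolic_bp: tuple[float, float]


_DEFAULT_GROUPS: dict[str, GroupLevels] = {
    "young": GroupLevels((11000, 2500), (4.9, 0.4), (115, 8)),
    "trained": GroupLevels((12500, 2200), (5.3, 0.5), (125, 10)),
    "normal": GroupLevels((8000, 2000), (5.9, 0.6), (132, 11)),
    "impaired": GroupLevels((4200, 1400), (6.9, 0.9), (141, 12)),
}


@dataclass
class MitoHealthSimParams:
    """Parameters of the 4-group validation-cohort generator.

    Defaults mirror the published design: group sizes 17/19/17/6 (young /
    trained / normal / impaired, summing to 59), young aged 20-30 and older
    adults 65-80, with group physiology ordered so trained older adults
    walk most and carry the lowest glucose and blood pressure.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"young": 17, "trained": 19, "normal": 17, "impaired": 6}
    )
    young_age_range: tuple[int, int] = (20, 30)
    older_age_range: tuple[int, int] = (65, 80)
    group_levels: dict[str, GroupLevels] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    male_fraction: float = 0.5
    metabolomics_subset_n: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        for name in GROUP_ORDER:
            if self.group_sizes.get(name, 0) < 1:
                raise ValueError(f"group {name!r} must have >= 1 participant")


def simulate_mitohealth_cohort(params: MitoHealthSimParams | None = None) -> pd.DataFrame:
    """Generate the labeled 4-group cohort (column ``group``)."""
    params = params or MitoHealthSimParams()
    rng = np.random.default_rng(params.seed)
    rows = []
    next_id = 1
    for group in GROUP_ORDER:
        n = params.group_sizes[group]
        lo, hi = (
            params.young_age_range if group == "young" else params.older_age_range
        )
        levels = params.group_levels[group]
        ages = rng.integers(lo, hi + 1, size=n)
        sexes = (rng.random(n) < params.male_fraction).astype(int)
        steps = np.clip(rng.normal(*levels.steps, size=n), 0.0, None)
        glucose = np.clip(rng.normal(*levels.glucose, size=n), 0.1, None)
        sysbp = rng.normal(*levels.systolic_bp, size=n)
        for i in range(n):
            rows.append(
                {
                    "id": next_id,
                    "group": group,
                    "age": int(ages[i]),
                    "is_85plus": False,
                    "sex": int(sexes[i]),
                    "glucose": float(glucose[i]),
                    "systolic_bp": float(sysbp[i]),
                    "avg_daily_steps": float(steps[i]),
                    "vital_status": "unknown",
                }
            )
            next_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plasma metabolome with planted deltaAge correlations
# ---------------------------------------------------------------------------

def reference_normalization(seed: int = 0, n: int = 3342, model=None):
    """Normalization table for the published clock, from a default cohort.

    Scoring with the published coefficients needs an NF table; this builds
    one by generating the default synthetic cohort and taking median raw
    predictions per age — a synthetic stand-in for the published per-age
    table, which is not redistributed here.
    """
    from .clock import PUBLISHED_MODEL, build_normalization

    cohort = simulate_nhanes_cohort(CohortSimParams(n_participants=n, seed=seed))
    return build_normalization(cohort, model or PUBLISHED_MODEL)


REQUIRED_METABOLITES = (
    "malate",
    "citrate",
    "isocitrate",
    "ribose 5-phosphate",
    "glucose",
    "nicotinamide",
)


def _default_metabolite_names(n: int) -> list[str]:
    names = list(REQUIRED_METABOLITES)
    i = len(names) + 1
    while len(names) < n:
        names.append(f"met_{i:03d}")
        i += 1
    return names[:n]


@dataclass
class MetabolomeSimParams:
    """Parameters of the plasma-metabolome generator.

    ``planted_signal`` maps metabolite name to a target Spearman rho between
    abundance and deltaAge among older adults; planting uses a Gaussian
    copula on the deltaAge ranks (latent correlation 2*sin(pi*rho/6)) and
    exponentiates, so abundances are strictly positive log-normals.
    ``planted_group_slopes`` adds a log-scale shift per ordinal health-group
    step (young=0 .. impaired=3) so a metabolite can also separate the four
    groups; ``planted_signal_by_sex`` plants a deltaAge correlation within
    one sex stratum only. Defaults plant the reported TCA-cycle/glucose
    pattern (citrate -0.61, isocitrate -0.47, malate -0.35, glucose +0.36)
    and a female-only nicotinamide association.
    """

    n_metabolites: int = 113
    names: list[str] = field(default_factory=list)
    planted_signal: dict[str, float] = field(
        default_factory=lambda: {
            "citrate": -0.61,
            "isocitrate": -0.47,
            "malate": -0.35,
            "glucose": 0.36,
            "ribose 5-phosphate": -0.45,
        }
    )
    planted_group_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "malate": -0.35,
            "ribose 5-phosphate": -0.40,
            "glucose": 0.35,
        }
    )
    planted_signal_by_sex: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"nicotinamide": {"female": -0.6}}
    )
    subset_per_group: dict[str, int] = field(
        default_factory=lambda: {"young": 12, "trained": 17, "normal": 16, "impaired": 3}
    )
    log_abundance_range: tuple[float, float] = (2.3, 6.9)  # ln units
    log_abundance_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.names:
            self.names = _default_metabolite_names(self.n_metabolites)
        if len(self.names) != len(set(self.names)):
            raise ValueError("metabolite names must be unique")
        for name, rho in self.planted_signal.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"planted rho for {name!r} must lie in (-1, 1)")


def _copula_scores(delta: np.ndarray, rho_s: float, rng: np.random.Generator):
    """Latent normal scores rank-correlated with ``delta`` at Spearman rho_s."""
    n = len(delta)
    ranks = stats.rankdata(delta, method="average")
    z_delta = stats.norm.ppf((ranks - 0.5) / n)
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    return r * z_delta + math.sqrt(1.0 - r**2) * rng.standard_normal(n)


def simulate_metabolome(
    scored_cohort: pd.DataFrame, params: MetabolomeSimParams | None = None
) -> pd.DataFrame:
    """Generate a positive abundance matrix joined to a scored cohort.

    ``scored_cohort`` must carry ``id``, ``group``, ``sex`` and ``delta_age``
    columns (older adults scored). Returns a DataFrame indexed like the
    metabolomics subset, first column ``sample_id``, one column per
    metabolite; planting happens on the older-adult rows only, young rows
    are independent noise around the same group-trend means.
    """
    params = params or MetabolomeSimParams()
    required = {"id", "group", "sex", "delta_age"}
    missing = required - set(scored_cohort.columns)
    if missing:
        raise ValueError(f"scored cohort lacks column(s): {sorted(missing)}")

    rng = np.random.default_rng(params.seed)
    subset_frames = []
    for group in GROUP_ORDER:
        members = scored_cohort[scored_cohort["group"] == group]
        take = params.subset_per_group.get(group, 0)
        if take > len(members):
            raise ValueError(
                f"metabolomics subset for {group!r} ({take}) exceeds group size "
                f"({len(members)})"
            )
        idx = rng.choice(len(members), size=take, replace=False)
        subset_frames.append(members.iloc[np.sort(idx)])
    subset = pd.concat(subset_frames, ignore_index=True)

    older = subset["group"] != "young"
    codes = subset["group"].map({g: i for i, g in enumerate(GROUP_ORDER)}).to_numpy()
    delta_older = subset.loc[older, "delta_age"].to_numpy()
    n = len(subset)

    columns: dict[str, np.ndarray] = {"sample_id": subset["id"].to_numpy()}
    lo, hi = params.log_abundance_range
    for name in params.names:
        z = rng.standard_normal(n)
        rho = params.planted_signal.get(name)
        if rho is not None:
            z[older.to_numpy()] = _copula_scores(delta_older, rho, rng)
        by_sex = params.planted_signal_by_sex.get(name)
        if by_sex is not None:
            for sex_label, sex_code in (("male", 1), ("female", 0)):
                rho_sex = by_sex.get(sex_label)
                if rho_sex is None:
                    continue
                stratum = older.to_numpy() & (subset["sex"].to_numpy() == sex_code)
                if stratum.sum() >= 2:
                    z[stratum] = _copula_scores(
                        subset.loc[stratum, "delta_age"].to_numpy(), rho_sex, rng
                    )
        slope = params.planted_group_slopes.get(name, 0.0)
        loc = rng.uniform(lo, hi)
        columns[name] = np.exp(
            loc + slope * (codes - codes.mean()) + params.log_abundance_sd * z
        )
    return pd.DataFrame(columns)
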