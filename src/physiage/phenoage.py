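"""Phenotypic age from blood biochemistry.

Phenotypic age ("PhenoAge") summarises nine routine blood biomarkers plus
calendar age into a single biological-age estimate. A linear predictor
``xb`` over the biomarkers is mapped to a 10-year mortality risk through a
Gompertz survival model, and that risk is re-expressed on the age axis:

    M        = 1 - exp(-exp(xb) * (exp(horizon_months * gamma) - 1) / gamma)
    PhenoAge = a + ln(b * ln(1 - M)) / c

with ``b < 0`` so the argument of the outer logarithm is positive. The
mapping is strictly increasing in ``xb``, which makes it exactly invertible:
given a target phenotypic age, one free biomarker can be solved for in
closed form. That inversion is what lets the synthetic-cohort generator
plant a known phenotypic age in a biomarker panel.

The default weights are transcribed reference values shipped in
``data/phenoage_levine.yaml``; they are external inputs to this package,
not results of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "BIOMARKER_NAMES",
    "BiomarkerPanel",
    "PhenoAgeConfig",
    "PhenoAgeDomainError",
    "UnitMismatchError",
    "compute_phenoage",
    "default_config",
    "default_panel",
    "invert_biomarker_for_phenoage",
    "load_phenoage_config",
    "save_phenoage_config",
]

#: Canonical biomarker field names, in the order they are reported.
BIOMARKER_NAMES = (
    "albumin",
    "creatinine",
    "glucose",
    "crp_ln",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)

#: Canonical units for each panel field (biomarkers + age).
CANONICAL_UNITS: Mapping[str, str] = {
    "albumin": "g/L",
    "creatinine": "umol/L",
    "glucose": "mmol/L",
    "crp_ln": "ln(mg/dL)",
    "lymphocyte_pct": "percent",
    "mcv": "fL",
    "rdw": "percent",
    "alp": "U/L",
    "wbc": "10^3 cells/uL",
    "age": "years",
}


class PhenoAgeDomainError(ValueError):
    """Mortality score fell outside (0, 1); the mapping is undefined."""


class UnitMismatchError(ValueError):
    """Panel units disagree with the configuration's declaration."""


@dataclass
class BiomarkerPanel:
    """One person's nine-biomarker panel plus calendar age.

    Fields may be scalars or equal-length numpy arrays; all computations
    broadcast. ``units`` optionally declares the units of each field and is
    checked against the config at compute time.
    """

    albumin: float  # g/L
    creatinine: float  # umol/L
    glucose: float  # mmol/L
    crp_ln: float  # ln(mg/dL)
    lymphocyte_pct: float  # percent, in [0, 100]
    mcv: float  # fL
    rdw: float  # percent
    alp: float  # U/L
    wbc: float  # 10^3 cells/uL
    age: float  # years
    units: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        lymph = np.asarray(self.lymphocyte_pct, dtype=float)
        if np.any(lymph < 0) or np.any(lymph > 100):
            raise ValueError("lymphocyte_pct must lie in [0, 100]")
        if np.any(np.asarray(self.age, dtype=float) <= 0):
            raise ValueError("age must be positive")


@dataclass
class PhenoAgeConfig:
    """Fully parameterized phenotypic-age mapping.

    ``weights`` holds one coefficient per biomarker, ``age_weight`` the
    calendar-age coefficient and ``intercept`` the constant of the linear
    predictor. ``gompertz_gamma`` (> 0) and ``horizon_months`` define the
    Gompertz risk integral; ``outer_a``, ``outer_b``, ``outer_c`` the final
    risk-to-years mapping. ``units`` declares the expected unit per field.
    """

    weights: dict[str, float]
    age_weight: float
    intercept: float
    gompertz_gamma: float
    horizon_months: float
    outer_a: float
    outer_b: float
    outer_c: float
    units: dict[str, str] = field(default_factory=lambda: dict(CANONICAL_UNITS))
    name: str = "unnamed"

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(BIOMARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown biomarker keys in weights: {sorted(unknown)}")
        missing = set(BIOMARKER_NAMES) - set(self.weights)
        if missing:
            raise ValueError(f"missing biomarker weights: {sorted(missing)}")
        if not self.gompertz_gamma > 0:
            raise ValueError("gompertz_gamma must be > 0")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be > 0")
        if self.outer_c == 0:
            raise ValueError("outer_c must be nonzero")

    # Risk integral over the horizon; reused by forward and inverse maps.
    @property
    def _risk_scale(self) -> float:
        g = self.gompertz_gamma
        return (math.exp(self.horizon_months * g) - 1.0) / g

    def linear_predictor(self, panel: BiomarkerPanel):
        xb = self.intercept + self.age_weight * np.asarray(panel.age, dtype=float)
        for name in BIOMARKER_NAMES:
            xb = xb + self.weights[name] * np.asarray(getattr(panel, name), dtype=float)
        return xb


def _check_units(panel: BiomarkerPanel, config: PhenoAgeConfig) -> None:
    if panel.units is None:
        return
    for key, unit in panel.units.items():
        declared = config.units.get(key)
        if declared is not None and unit != declared:
            raise UnitMismatchError(
                f"panel declares {key!r} in {unit!r} but config expects {declared!r}"
            )


def compute_phenoage(panel: BiomarkerPanel, config: PhenoAgeConfig):
    """Phenotypic age in years for a biomarker panel.

    Strictly increasing in every biomarker with a positive weight. Raises
    :class:`PhenoAgeDomainError` when the mortality score degenerates to 0
    or 1 (never returns a silent NaN), and :class:`UnitMismatchError` when
    the panel's declared units disagree with the config.
    """
    _check_units(panel, config)
    xb = config.linear_predictor(panel)
    # M in (0,1); log1p/expm1 keep the tails accurate.
    log_surv = -np.exp(xb) * config._risk_scale  # = ln(1 - M), < 0
    if np.any(~np.isfinite(log_surv)) or np.any(log_surv == 0.0):
        raise PhenoAgeDomainError("mortality score outside (0, 1)")
    inner = config.outer_b * log_surv  # > 0 when outer_b < 0
    if np.any(inner <= 0):
        raise PhenoAgeDomainError("outer mapping undefined: b * ln(1-M) <= 0")
    years = config.outer_a + np.log(inner) / config.outer_c
    if np.any(~np.isfinite(years)):
        raise PhenoAgeDomainError("phenotypic age not finite")
    return years if np.ndim(years) else float(years)


def invert_biomarker_for_phenoage(
    target_phenoage,
    panel_defaults: BiomarkerPanel,
    config: PhenoAgeConfig,
    free_biomarker: str = "rdw",
) -> BiomarkerPanel:
    """Solve one biomarker so the panel maps exactly to ``target_phenoage``.

    All other fields keep their values from ``panel_defaults``. The mapping
    is affine in ``xb`` after inverting the two outer transforms, so the
    solution is closed-form and exact to floating point; round-trip error is
    far below the 1e-6-year contract. ``target_phenoage`` may be an array,
    in which case the free biomarker is solved elementwise.
    """
    if free_biomarker not in BIOMARKER_NAMES:
        raise ValueError(f"unknown biomarker {free_biomarker!r}")
    w = config.weights[free_biomarker]
    if w == 0:
        raise ValueError(
            f"target unreachable: {free_biomarker!r} has zero weight in this config"
        )
    target = np.asarray(target_phenoage, dtype=float)
    # Invert outer mapping: PhenoAge -> ln(1-M) -> xb.
    log_surv = np.exp(config.outer_c * (target - config.outer_a)) / config.outer_b
    if np.any(log_surv >= 0):
        raise PhenoAgeDomainError("target implies survival probability >= 1")
    xb = np.log(-log_surv / config._risk_scale)
    if np.any(~np.isfinite(xb)):
        raise PhenoAgeDomainError("target unreachable for any finite biomarker value")
    # Remove every fixed term, leaving w * free.
    rest = config.intercept + config.age_weight * np.asarray(panel_defaults.age, float)
    for name in BIOMARKER_NAMES:
        if name != free_biomarker:
            rest = rest + config.weights[name] * np.asarray(
                getattr(panel_defaults, name), float
            )
    value = (xb - rest) / w
    if np.ndim(value) == 0:
        value = float(value)
    return replace(panel_defaults, **{free_biomarker: value})


# ---------------------------------------------------------------------------
# Config file I/O (flat YAML schema, lossless round-trip)
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "intercept",
    "weights",
    "age_weight",
    "gompertz_gamma",
    "horizon_months",
    "outer_a",
    "outer_b",
    "outer_c",
)


def load_phenoage_config(path: str | Path) -> PhenoAgeConfig:
    """Read a phenotypic-age config from its YAML schema, validating keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ValueError(f"config {path} missing required field(s): {missing}")
    known = set(_REQUIRED_KEYS) | {"units", "name"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config {path} has unknown field(s): {sorted(unknown)}")
    return PhenoAgeConfig(
        weights={k: float(v) for k, v in raw["weights"].items()},
        age_weight=float(raw["age_weight"]),
        intercept=float(raw["intercept"]),
        gompertz_gamma=float(raw["gompertz_gamma"]),
        horizon_months=float(raw["horizon_months"]),
        outer_a=float(raw["outer_a"]),
        outer_b=float(raw["outer_b"]),
        outer_c=float(raw["outer_c"]),
        units=dict(raw.get("units", CANONICAL_UNITS)),
        name=str(raw.get("name", "unnamed")),
    )


def save_phenoage_config(config: PhenoAgeConfig, path: str | Path) -> None:
    """Write a config so that ``load_phenoage_config`` restores it exactly."""
    payload = {
        "name": config.name,
        "intercept": config.intercept,
        "weights": dict(config.weights),
        "age_weight": config.age_weight,
        "gompertz_gamma": config.gompertz_gamma,
        "horizon_months": config.horizon_months,
        "outer_a": config.outer_a,
        "outer_b": config.outer_b,
        "outer_c": config.outer_c,
        "units": dict(config.units),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_config() -> PhenoAgeConfig:
    """The shipped reference mapping (externally sourced constants)."""
    ref = resources.files("physiage").joinpath("data/phenoage_levine.yaml")
    with resources.as_file(ref) as path:
        return load_phenoage_config(path)


def default_panel(age: float = 50.0) -> BiomarkerPanel:
    """A mid-normal adult panel used as the inversion anchor.

    Values sit near clinical reference midpoints; only the free biomarker is
    moved when planting a target phenotypic age.
    """
    return BiomarkerPanel(
        albumin=43.0,
        creatinine=80.0,
        glucose=5.2,
        crp_ln=math.log(0.1),
        lymphocyte_pct=30.0,
        mcv=90.0,
        rdw=13.0,
        alp=70.0,
        wbc=6.0,
        age=age,
    )
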