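"""File I/O, configuration and the end-to-end pipeline driver.

The pipeline mirrors the clock-building strategy: acquire a cohort
(simulated or read from CSV), apply completeness/age QC and step-outlier
removal, compute the phenotypic-age target from the biomarker panel, split
by sex into train/test, fit the clock, build the normalization table, score
the held-out data, and run the validation battery; when a metabolite matrix
is available, run the decelerated-aging screens.

All randomness flows from one top-level seed expanded into named per-stage
streams, so a stage rerun with its own stream reproduces the full run's
behaviour. CSV dialect is fixed: comma, "." decimal, UTF-8, one header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clock, metabolites, synthetic_cohort, validation
from .phenoage import BIOMARKER_NAMES, BiomarkerPanel, compute_phenoage, default_config

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "attach_phenoage",
    "read_cohort",
    "read_metabolite_matrix",
    "run_pipeline",
    "write_cohort",
]

#: Canonical cohort column names (subset used depends on the analysis).
CANONICAL_COLUMNS = (
    "id",
    "age",
    "is_85plus",
    "sex",
    "glucose",
    "systolic_bp",
    "diastolic_bp",
    "resting_hr",
    "bmi",
    "avg_daily_steps",
    "vital_status",
)

REQUIRED_COLUMNS = ("age", "sex", "glucose", "systolic_bp", "avg_daily_steps")


def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a participant CSV into canonical columns and units.

    ``column_map`` renames source columns to canonical names (e.g. NHANES
    variable names); ``units`` may declare ``glucose: mg/dL``, in which case
    values are divided by 18.016 and the conversion is logged.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"unmapped required column(s): {missing}")
    for col in REQUIRED_COLUMNS:
        if not np.issubdtype(table[col].dtype, np.number):
            try:
                table[col] = pd.to_numeric(table[col])
            except (TypeError, ValueError) as err:
                raise ValueError(f"column {col!r} is not numeric: {err}") from err
    if units and units.get("glucose") == "mg/dL":
        table["glucose"] = table["glucose"] / clock.MG_PER_DL_PER_MMOL_PER_L
        logger.info("glucose converted from mg/dL to mmol/L (/18.016)")
    if "id" not in table.columns:
        table["id"] = np.arange(1, len(table) + 1)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.4f")


def read_metabolite_matrix(path: str | Path) -> pd.DataFrame:
    """Metabolite CSV: rows = samples, first column sample id."""
    frame = pd.read_csv(path)
    frame = frame.rename(columns={frame.columns[0]: "sample_id"})
    names = list(frame.columns[1:])
    if len(names) != len(set(names)):
        raise ValueError("duplicated metabolite names in matrix")
    values = frame[names].to_numpy(dtype=float)
    if np.any(values[~np.isnan(values)] <= 0):
        raise ValueError("metabolite abundances must be strictly positive")
    return frame


def attach_phenoage(table: pd.DataFrame, config=None) -> pd.DataFrame:
    """Compute the phenotypic-age column from the biomarker panel columns."""
    config = config or default_config()
    missing = [c for c in BIOMARKER_NAMES if c not in table.columns]
    if missing:
        raise KeyError(f"biomarker column(s) absent: {missing}")
    panel = BiomarkerPanel(
        **{name: table[name].to_numpy(dtype=float) for name in BIOMARKER_NAMES},
        age=table["age"].to_numpy(dtype=float),
    )
    out = table.copy()
    out["phenoage"] = compute_phenoage(panel, config)
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Each data source block carries exactly one of ``path`` (read a CSV,
    with optional ``column_map``/``units``) or ``simulate`` (generator
    parameters). ``seed`` feeds every per-stage random stream.
    """

    seed: int = 1
    outdir: str = "physiage_out"
    cohort: dict = field(default_factory=lambda: {"simulate": {}})
    mortality: dict = field(default_factory=dict)
    split: dict = field(default_factory=lambda: {"train_fraction": 0.8})
    step_outlier_k: float = 1.5
    cutoffs: dict = field(
        default_factory=lambda: {"p_delta": 0.05, "p_group": 0.01}
    )
    mitohealth: dict | None = None
    metabolome: dict | None = None
    robustness_seeds: list[int] = field(default_factory=lambda: list(range(1, 11)))

    def __post_init__(self) -> None:
        for name, block in (("cohort", self.cohort), ("mitohealth", self.mitohealth),
                            ("metabolome", self.metabolome)):
            if block is None:
                continue
            if ("path" in block) == ("simulate" in block):
                raise ValueError(
                    f"{name} block must carry exactly one of 'path' or 'simulate'"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the root seed."""
    names = ("cohort", "mortality", "split", "mitohealth", "metabolome", "extra")
    child = np.random.SeedSequence(root).spawn(len(names))[names.index(stage)]
    return int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Run report and driver
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Seeds, per-stage row counts, exclusion tallies, headline statistics."""

    seed: int
    stage_counts: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _acquire_cohort(config: PipelineConfig) -> pd.DataFrame:
    block = config.cohort
    if "path" in block:
        return read_cohort(
            block["path"], block.get("column_map"), block.get("units")
        )
    params = synthetic_cohort.CohortSimParams(
        seed=_stage_seed(config.seed, "cohort"), **block.get("simulate", {})
    )
    cohort = synthetic_cohort.simulate_nhanes_cohort(params)
    hazard = synthetic_cohort.HazardParams(**config.mortality)
    return synthetic_cohort.simulate_mortality(
        cohort, hazard, seed=_stage_seed(config.seed, "mortality")
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute qc -> split -> phenoage -> fit -> NF -> score -> validate
    (plus metabolite screens when a matrix is configured), writing all
    artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    stage = "acquire cohort"
    try:
        cohort = _acquire_cohort(config)
        report.stage_counts["input"] = len(cohort)

        stage = "qc"
        filtered, held_85, qc_report = clock.qc_filter(cohort)
        filtered = clock.remove_step_outliers(filtered, k=config.step_outlier_k)
        report.qc = asdict(qc_report)
        report.stage_counts["after_qc"] = len(filtered)

        stage = "phenoage"
        if all(c in filtered.columns for c in BIOMARKER_NAMES):
            filtered = attach_phenoage(filtered)
        elif "phenoage" not in filtered.columns:
            raise KeyError("no biomarker panel and no phenoage column")

        stage = "split"
        train, test = clock.split_train_test(
            filtered,
            config.split.get("train_fraction", 0.8),
            seed=_stage_seed(config.seed, "split"),
        )
        report.stage_counts["train"] = len(train)
        report.stage_counts["test"] = len(test)

        stage = "fit"
        fit = clock.fit_model(train)
        report.fit = {
            "intercept": fit.model.intercept,
            "coefficients": dict(fit.model.coefs),
            "pvalues": fit.pvalues,
            "rsquared": fit.rsquared,
        }
        clock.save_model(fit.model, outdir / "model.yaml")

        stage = "normalization"
        nf = clock.build_normalization(train, fit.model)
        nf.to_csv(outdir / "nf_table.csv")

        stage = "score"
        scored_train = clock.score_table(fit.model, nf, train)
        scored_test = clock.score_table(fit.model, nf, test)
        write_cohort(scored_test, outdir / "scored_test.csv")

        stage = "validate"
        stats_block: dict = {
            "train_rmse_raw": validation.rmse(
                scored_train["raw_prediction"], scored_train["age"]
            ),
            "train_rmse_physiage": validation.rmse(
                scored_train["physiage"], scored_train["age"]
            ),
            "test_rmse_physiage": validation.rmse(
                scored_test["physiage"], scored_test["age"]
            ),
        }
        if (scored_test["vital_status"] == "deceased").sum() >= 2:
            contrast = validation.mortality_contrast(scored_test)
            stats_block["mortality"] = asdict(contrast)
        if len(held_85) >= 4 and (held_85["vital_status"] == "deceased").sum() >= 2:
            stats_block["mortality_85plus"] = asdict(
                validation.score_85plus(fit.model, nf, held_85)
            )
        r_df, p_df, _ = validation.cross_correlation(
            filtered, ["age", "glucose", "systolic_bp", "avg_daily_steps"]
        )
        r_df.to_csv(outdir / "cross_correlation_r.csv")
        p_df.to_csv(outdir / "cross_correlation_p.csv")
        if (scored_test["vital_status"] == "deceased").sum() >= 2:
            abl = validation.ablation(train, test)
            stats_block["ablation"] = [
                {
                    "omitted": a.omitted,
                    "test_rmse": a.test_rmse,
                    "mortality_p": a.mortality_p,
                }
                for a in abl
            ]
        if len(config.robustness_seeds) >= 2:
            rob = validation.split_robustness(filtered, config.robustness_seeds)
            stats_block["split_robustness"] = {
                "seeds": rob.seeds,
                "rmses": rob.rmses,
                "min": rob.min,
                "median": rob.median,
                "max": rob.max,
            }
        report.statistics = stats_block

        stage = "metabolites"
        if config.mitohealth is not None:
            mh_params = synthetic_cohort.MitoHealthSimParams(
                seed=_stage_seed(config.seed, "mitohealth"),
                **config.mitohealth.get("simulate", {}),
            )
            mito = synthetic_cohort.simulate_mitohealth_cohort(mh_params)
            scored_mito = clock.score_table(fit.model, nf, mito)
            write_cohort(scored_mito, outdir / "scored_mitohealth.csv")
            report.statistics["mitohealth_median_delta_age"] = (
                scored_mito.groupby("group")["delta_age"].median().to_dict()
            )
            if config.metabolome is not None:
                if "path" in config.metabolome:
                    matrix = read_metabolite_matrix(config.metabolome["path"])
                else:
                    mb_params = synthetic_cohort.MetabolomeSimParams(
                        seed=_stage_seed(config.seed, "metabolome"),
                        **config.metabolome.get("simulate", {}),
                    )
                    matrix = synthetic_cohort.simulate_metabolome(scored_mito, mb_params)
                matrix.to_csv(outdir / "metabolites.csv", index=False)
                older = scored_mito[scored_mito["group"] != "young"]
                older_matrix = matrix[
                    matrix["sample_id"].isin(older["id"])
                ].reset_index(drop=True)
                delta_res = metabolites.correlate_delta(older_matrix, older)
                groups = dict(zip(scored_mito["id"], scored_mito["group"]))
                group_res = metabolites.correlate_groups(matrix, groups)
                signature = metabolites.select_signature(
                    delta_res,
                    group_res,
                    config.cutoffs.get("p_delta", 0.05),
                    config.cutoffs.get("p_group", 0.01),
                )
                delta_res.to_csv(outdir / "screen_delta.csv", index=False)
                group_res.to_csv(outdir / "screen_groups.csv", index=False)
                signature.to_csv(outdir / "signature.csv", index=False)
                report.statistics["signature_intersection"] = signature.loc[
                    signature["in_intersection"], "metabolite"
                ].tolist()
        else:
            report.notes.append("metabolite screens skipped: no matrix configured")
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        report.notes.append(f"aborted at stage {stage!r}: {err}")
        report.to_json(outdir / "report.json")
        raise

    report.to_json(outdir / "report.json")
    return report
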