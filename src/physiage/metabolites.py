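"""Plasma-metabolomics decelerated-aging screen.

Given a positive abundance matrix (rows = samples, columns = metabolites)
joined to scored participants, the screen correlates each metabolite with
(1) deltaAge among older adults and (2) the ordinal health groups
(young=0 < trained=1 < normal=2 < impaired=3) over all participants, both
Spearman by default. A signature is selected with raw-p cutoffs (deltaAge
screen p < 0.05, group screen p < 0.01, strict inequalities) and their
intersection. Group contrasts use the tie-corrected Kruskal-Wallis test
with optional pairwise rank-sum p values; the sex-stratified screen runs
the deltaAge correlation separately in males and females (Pearson by
default for that analysis).

No multiple-testing correction enters the selection; a Benjamini-Hochberg
FDR column is emitted alongside for reference only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_CODES",
    "ZeroVarianceError",
    "correlate_delta",
    "correlate_groups",
    "group_contrast",
    "select_signature",
    "sex_stratified_signature",
    "spearman",
]

#: Ordinal coding of the health groups along the health-decline ordering.
GROUP_CODES: Mapping[str, int] = {"young": 0, "trained": 1, "normal": 2, "impaired": 3}


class ZeroVarianceError(ValueError):
    """Rank correlation undefined: one input has zero rank variance."""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p value.

    rho is the Pearson correlation of mid-ranks; ties are allowed. Raises
    :class:`ZeroVarianceError` (rather than returning NaN) when either
    input has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise ZeroVarianceError("zero rank variance; rho undefined")
    result = stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


def _pearson(x, y) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("zero variance; correlation undefined")
    result = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(result.statistic), float(result.pvalue)


_METHODS = {"spearman": spearman, "pearson": _pearson}


def _metabolite_columns(matrix: pd.DataFrame) -> list[str]:
    cols = [c for c in matrix.columns if c != "sample_id"]
    if len(cols) != len(set(cols)):
        raise ValueError("duplicated metabolite names")
    return cols


def _screen(
    matrix: pd.DataFrame, target: np.ndarray, method: str
) -> pd.DataFrame:
    corr = _METHODS[method]
    rows = []
    for name in _metabolite_columns(matrix):
        values = matrix[name].to_numpy(dtype=float)
        keep = ~np.isnan(values)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s: %d missing sample(s) dropped pairwise", name, dropped)
        try:
            rho, p = corr(values[keep], target[keep])
            degenerate = False
        except ZeroVarianceError:
            rho, p, degenerate = np.nan, np.nan, True
        rows.append(
            {
                "metabolite": name,
                "rho": rho,
                "p": p,
                "n": int(keep.sum()),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _join(matrix: pd.DataFrame, scored: pd.DataFrame, column: str) -> np.ndarray:
    """Resolve each matrix sample to the participant's value of ``column``."""
    lookup = scored.set_index("id")[column]
    ids = matrix["sample_id"]
    unknown = ids[~ids.isin(lookup.index)]
    if len(unknown):
        raise ValueError(f"unjoinable sample id(s): {sorted(unknown.tolist())}")
    return lookup.loc[ids].to_numpy(dtype=float)


def correlate_delta(
    matrix: pd.DataFrame, scored_older: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """Per-metabolite correlation with deltaAge among older adults.

    ``matrix`` should contain only older-adult samples; every sample id
    must resolve to a row of ``scored_older`` (columns id, delta_age).
    """
    delta = _join(matrix, scored_older, "delta_age")
    return _screen(matrix, delta, method)


def correlate_groups(
    matrix: pd.DataFrame, groups: Mapping[object, str], method: str = "spearman"
) -> pd.DataFrame:
    """Per-metabolite correlation with the ordinal health-group codes."""
    labels = [groups.get(s) for s in matrix["sample_id"]]
    unknown = [
        (s, lbl)
        for s, lbl in zip(matrix["sample_id"], labels)
        if lbl not in GROUP_CODES
    ]
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown[:5]}")
    codes = np.array([GROUP_CODES[lbl] for lbl in labels], dtype=float)
    return _screen(matrix, codes, method)


def select_signature(
    delta_results: pd.DataFrame,
    group_results: pd.DataFrame,
    p_delta_cut: float = 0.05,
    p_group_cut: float = 0.01,
) -> pd.DataFrame:
    """Flag metabolites passing each screen's cutoff and their intersection.

    Cutoffs are strict inequalities. The returned table carries the cutoffs
    as attrs, sorts intersection members first by |rho_delta| descending,
    and adds Benjamini-Hochberg FDR columns for reference (never used in
    the selection itself).
    """
    d = delta_results.rename(columns={"rho": "rho_delta", "p": "p_delta"})
    g = group_results.rename(columns={"rho": "rho_group", "p": "p_group"})
    if set(d["metabolite"]) != set(g["metabolite"]):
        raise ValueError("metabolite universes differ between the two screens")
    merged = d[["metabolite", "rho_delta", "p_delta"]].merge(
        g[["metabolite", "rho_group", "p_group"]], on="metabolite", validate="1:1"
    )
    merged["in_delta_set"] = merged["p_delta"] < p_delta_cut
    merged["in_group_set"] = merged["p_group"] < p_group_cut
    merged["in_intersection"] = merged["in_delta_set"] & merged["in_group_set"]
    for col in ("p_delta", "p_group"):
        finite = merged[col].notna()
        fdr = np.full(len(merged), np.nan)
        if finite.any():
            fdr[finite.to_numpy()] = multipletests(
                merged.loc[finite, col], method="fdr_bh"
            )[1]
        merged[f"{col}_fdr_bh"] = fdr
    merged = merged.sort_values(
        ["in_intersection", "rho_delta"],
        key=lambda s: s.abs() if s.name == "rho_delta" else s,
        ascending=False,
    ).reset_index(drop=True)
    merged.attrs["p_delta_cut"] = p_delta_cut
    merged.attrs["p_group_cut"] = p_group_cut
    return merged


@dataclass
class GroupContrast:
    """Tie-corrected Kruskal-Wallis contrast across health groups."""

    h_statistic: float
    p_value: float
    degenerate: bool
    pairwise_p: dict[tuple[str, str], float] | None = None


def group_contrast(
    values: Sequence[float],
    groups: Sequence[str],
    pairwise: bool = False,
) -> GroupContrast:
    """Kruskal-Wallis H and asymptotic p across the labeled groups.

    All-identical values are a degenerate case reported as H = 0, p = 1.
    With ``pairwise=True``, unadjusted two-sided rank-sum p values for each
    group pair are attached.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    unique = [g for g in GROUP_CODES if g in labels] or list(pd.unique(labels))
    if len(unique) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in unique]
    if any(len(s) < 1 for s in samples):
        raise ValueError("every group needs at least 1 value")
    if np.ptp(values) == 0:
        logger.info("group contrast degenerate: all values identical")
        return GroupContrast(0.0, 1.0, True)
    h, p = stats.kruskal(*samples)
    pairs = None
    if pairwise:
        pairs = {}
        for i in range(len(unique)):
            for j in range(i + 1, len(unique)):
                a, b = samples[i], samples[j]
                if np.ptp(np.concatenate([a, b])) == 0:
                    pairs[(unique[i], unique[j])] = 1.0
                else:
                    pairs[(unique[i], unique[j])] = float(
                        stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                    )
    return GroupContrast(float(h), float(p), False, pairs)


def sex_stratified_signature(
    matrix: pd.DataFrame,
    scored_older: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.05,
    min_n: int = 4,
) -> pd.DataFrame:
    """DeltaAge correlation per metabolite, separately in males and females.

    ``scored_older`` needs columns id, sex (1=male, 0=female), delta_age.
    Each metabolite is classed ``both`` / ``male_only`` / ``female_only`` /
    ``neither`` at p < ``alpha`` per stratum; a stratum smaller than
    ``min_n`` is flagged unreliable and never counted significant.
    """
    delta = _join(matrix, scored_older, "delta_age")
    sex = _join(matrix, scored_older, "sex")
    strata = {"male": sex == 1, "female": sex == 0}
    if any(mask.sum() == 0 for mask in strata.values()):
        raise ValueError("both sex strata must be non-empty")
    corr = _METHODS[method]
    rows = []
    for name in _metabolite_columns(matrix):
        values = matrix[name].to_numpy(dtype=float)
        row: dict[str, object] = {"metabolite": name}
        significant = {}
        for label, mask in strata.items():
            keep = mask & ~np.isnan(values)
            if keep.sum() < min_n:
                logger.warning("%s: %s stratum below n=%d, unreliable", name, label, min_n)
                row[f"rho_{label}"], row[f"p_{label}"] = np.nan, np.nan
                row[f"unreliable_{label}"] = True
                significant[label] = False
                continue
            try:
                rho, p = corr(values[keep], delta[keep])
            except ZeroVarianceError:
                rho, p = np.nan, np.nan
            row[f"rho_{label}"], row[f"p_{label}"] = rho, p
            row[f"unreliable_{label}"] = False
            significant[label] = bool(p < alpha) if np.isfinite(p) else False
        row["class"] = {
            (True, True): "both",
            (True, False): "male_only",
            (False, True): "female_only",
            (False, False): "neither",
        }[(significant["male"], significant["female"])]
        rows.append(row)
    return pd.DataFrame(rows)
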