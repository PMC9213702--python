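"""Differential-abundance statistics shared by species- and reaction-level analyses.

The workflow for each feature (an MSP — metagenomic species pan-genome — or a
metabolic reaction) is a two-tailed Wilcoxon rank-sum test between case and
control samples, Benjamini-Hochberg (BH) step-up adjustment across features,
and an enrichment direction from the comparison of group means.  Species
selection additionally applies a two-step rule: FDR below threshold AND a
distinct median pattern, one group median exactly zero and the other strictly
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_two_sided",
    "benjamini_hochberg",
    "differential_table",
    "select_significant_msps",
    "enrichment_direction",
    "aggregate_by_phylum",
    "unique_union",
    "read_abundance",
    "read_metadata",
    "DISEASE_ENRICHED",
    "CONTROL_ENRICHED",
]

DISEASE_ENRICHED = "disease-enriched"
CONTROL_ENRICHED = "control-enriched"

#: pooled sample size at or below which the exact null distribution is used
EXACT_N_MAX = 20


def wilcoxon_two_sided(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact permutation null when the pooled sample size is at most
    ``EXACT_N_MAX`` and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_N_MAX and not ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_masks(meta: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    groups = meta.loc[list(sample_ids), "group"]
    case = (groups == "case").to_numpy()
    control = (groups == "control").to_numpy()
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("both case and control groups must be present")
    return case, control


def differential_table(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    min_group_size: int = 2,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-feature Wilcoxon + BH differential summary.

    ``table`` is samples x features; ``meta`` maps sample_id to a
    case/control ``group``.  Returns one row per feature with p_value, fdr,
    group medians and means, log2 fold_change (with pseudo-count half the
    smallest nonzero table value unless given), and enrichment direction.
    """
    case, control = _group_masks(meta, table.index)
    if case.sum() < min_group_size or control.sum() < min_group_size:
        raise ValueError(
            f"each group needs >= {min_group_size} samples "
            f"(case={int(case.sum())}, control={int(control.sum())})"
        )
    values = table.to_numpy(dtype=float)
    if pseudocount is None:
        nonzero = values[values > 0]
        pseudocount = 0.5 * float(nonzero.min()) if nonzero.size else 1e-9

    rows = []
    for j, feature in enumerate(table.columns):
        xv, yv = values[case, j], values[control, j]
        if np.ptp(np.concatenate([xv, yv])) == 0:
            p = 1.0  # constant feature carries no rank information
        else:
            p = wilcoxon_two_sided(xv, yv)
        mean_case, mean_control = float(xv.mean()), float(yv.mean())
        rows.append(
            {
                "feature_id": feature,
                "p_value": p,
                "median_case": float(np.median(xv)),
                "median_control": float(np.median(yv)),
                "mean_case": mean_case,
                "mean_control": mean_control,
                "fold_change": float(
                    np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
                ),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["direction"] = np.where(
        out["mean_case"] > out["mean_control"], DISEASE_ENRICHED, CONTROL_ENRICHED
    )
    return out[
        [
            "feature_id",
            "p_value",
            "fdr",
            "median_case",
            "median_control",
            "mean_case",
            "mean_control",
            "fold_change",
            "direction",
        ]
    ]


def enrichment_direction(mean_case: float, mean_control: float) -> str:
    """Disease-enriched iff the case mean strictly exceeds the control mean.

    Exact ties are labelled control-enriched (strict-inequality rule).
    """
    return DISEASE_ENRICHED if mean_case > mean_control else CONTROL_ENRICHED


def select_significant_msps(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-step species selection.

    A feature is selected iff (1) its BH FDR is below ``fdr_threshold`` and
    (2) exactly one of the two group medians equals 0 while the other is
    strictly positive.  Returns the differential rows of selected features.
    """
    diff = differential_table(table, meta)
    med_case = diff["median_case"].to_numpy()
    med_control = diff["median_control"].to_numpy()
    median_rule = ((med_case == 0) & (med_control > 0)) | ((med_control == 0) & (med_case > 0))
    keep = (diff["fdr"] < fdr_threshold) & median_rule
    return diff[keep].reset_index(drop=True)


def aggregate_by_phylum(table: pd.DataFrame, phylum_of: dict[str, str]) -> pd.DataFrame:
    """Sum member feature abundances into phylum-level columns per sample.

    Features missing from ``phylum_of`` are pooled under ``unclassified``.
    """
    labels = [phylum_of.get(f, "unclassified") for f in table.columns]
    return table.T.groupby(pd.Index(labels, name="phylum")).sum().T


def unique_union(per_disease_selected: dict[str, set]) -> set:
    """Union of per-disease selected feature sets with duplicates removed."""
    if not per_disease_selected:
        raise ValueError("at least one selected set is required")
    out: set = set()
    for s in per_disease_selected.values():
        out |= set(s)
    return out


# -- tabular I/O ------------------------------------------------------------


def read_abundance(path, relative: bool = True) -> pd.DataFrame:
    """Read a samples x features abundance TSV (first column ``sample_id``)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    if relative and (values.sum(axis=1) > 1 + 1e-6).any():
        raise ValueError(f"{path}: per-sample relative abundances exceed 1")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with group/disease/cohort/bmi/age/sex columns."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return meta
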