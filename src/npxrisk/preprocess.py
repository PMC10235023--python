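"""Measurement-level preprocessing for NPX-style protein matrices.

Three steps, applied in order: (1) values censored below an assay's limit of
detection (LOD) are replaced by LOD/sqrt(2), following the platform
manufacturer's recommendation; (2) proteins measured by more than one assay
(duplicate panels) are resolved to a single column, keeping the assay with
the lowest missingness and, on ties, the highest variance; (3) each protein
is standardized to mean 0, SD 1 within each cohort.  A QC report records the
percentage of below-LOD values per cohort and flags proteins with >= 20%
below-LOD values pooled across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOD_QC_MAX_PCT = 20.0  # proteins with >= this % below LOD (pooled) fail QC

__all__ = [
    "substitute_lod",
    "resolve_duplicates",
    "standardize_within_cohort",
    "qc_report",
    "preprocess_study",
    "PreprocessResult",
]


def substitute_lod(matrix: pd.DataFrame, lod_mask: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Replace below-LOD entries by LOD/sqrt(2); other entries unchanged.

    Raises ``ValueError`` if any assay with masked values lacks a finite LOD.
    A non-positive LOD is substituted as stated (LOD/sqrt(2)) with a warning,
    since the rule's limit is degenerate there.
    """
    out = matrix.copy()
    lods = annotations["lod"]
    for col in matrix.columns:
        mask = lod_mask[col].to_numpy(dtype=bool)
        if not mask.any():
            continue
        lod = lods.get(col, np.nan)
        if not np.isfinite(lod):
            raise ValueError(f"assay {col!r} has below-LOD values but no finite LOD")
        if lod <= 0:
            logger.warning("assay %s has non-positive LOD %.3g; substituting LOD/sqrt(2) anyway", col, lod)
        out.loc[mask, col] = lod / np.sqrt(2.0)
    return out


def resolve_duplicates(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep one assay per protein and rename columns to protein ids.

    Among duplicate assays of a protein, the one with the lowest missingness
    is retained; ties are broken by the highest variance.  Missingness and
    variance are computed on the samples belonging to cohorts in which every
    duplicate of the group was measured, so the comparison is head-to-head.
    Returns the reduced matrix (columns = protein ids) and a decision table
    (protein, chosen assay, chosen panel, n candidates).
    """
    groups = annotations.groupby("protein").groups
    decisions = []
    keep: dict[str, str] = {}
    for protein, assays in groups.items():
        assays = [a for a in assays if a in matrix.columns]
        if not assays:
            continue
        if len(assays) == 1:
            keep[protein] = assays[0]
        else:
            common_cohorts = None
            for a in assays:
                cs = set(str(annotations.loc[a, "cohorts"]).split(";")) if "cohorts" in annotations else None
                common_cohorts = cs if common_cohorts is None else (common_cohorts & cs if cs else common_cohorts)
            if subjects is not None and common_cohorts:
                rows = subjects.loc[subjects["cohort"].isin(common_cohorts), "sample_id"]
                sub = matrix.loc[matrix.index.intersection(rows)]
            else:
                sub = matrix
            stats = []
            for a in assays:
                col = sub[a]
                stats.append((col.isna().mean(), -np.nanvar(col.to_numpy(), ddof=1), a))
            stats.sort()
            keep[protein] = stats[0][2]
        decisions.append(
            {
                "protein": protein,
                "chosen_assay": keep[protein],
                "chosen_panel": annotations.loc[keep[protein], "panel"],
                "n_assays": len(assays),
            }
        )
    out = matrix[[keep[p] for p in keep]].copy()
    out.columns = list(keep)
    return out, pd.DataFrame(decisions)


def standardize_within_cohort(matrix: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each protein to mean 0, SD 1 within each cohort.

    Missing entries stay missing.  A protein with zero variance within a
    cohort is set to missing in that cohort and logged.
    """
    cohorts = subjects.set_index("sample_id")["cohort"].reindex(matrix.index)
    out = matrix.copy()
    for cohort, idx in matrix.groupby(cohorts.to_numpy()).groups.items():
        block = matrix.loc[idx]
        mean = block.mean()
        sd = block.std(ddof=1)
        zero = sd.index[(sd == 0) | (sd.isna() & block.notna().any())]
        for col in zero:
            logger.warning("protein %s has zero variance in cohort %s; excluded there", col, cohort)
        z = (block - mean) / sd.replace(0.0, np.nan)
        z[list(zero)] = np.nan
        out.loc[idx] = z
    return out


def qc_report(
    lod_mask: pd.DataFrame,
    annotations: pd.DataFrame,
    subjects: pd.DataFrame,
    decisions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-assay QC: % below LOD per cohort and pooled, pass flag, duplicate choice.

    Percentages are over measured values only (cohorts that did not measure
    an assay do not contribute).  ``passes_lod_qc`` is True when the pooled
    percentage is strictly below 20%.
    """
    cohorts = subjects.set_index("sample_id")["cohort"].reindex(lod_mask.index)
    measured = lod_mask.notna()
    rows = []
    for assay in lod_mask.columns:
        mask = lod_mask[assay]
        row = {"assay": assay, "protein": annotations.loc[assay, "protein"]}
        avail = str(annotations.loc[assay, "cohorts"]).split(";") if "cohorts" in annotations else []
        n_meas, n_below = 0, 0
        for cohort, idx in cohorts.groupby(cohorts).groups.items():
            if avail and cohort not in avail:
                row[f"pct_below_lod_{cohort}"] = np.nan
                continue
            m = mask.loc[idx]
            row[f"pct_below_lod_{cohort}"] = 100.0 * m.mean()
            n_meas += len(m)
            n_below += int(m.sum())
        pooled = 100.0 * n_below / n_meas if n_meas else np.nan
        row["pct_below_lod_pooled"] = pooled
        row["passes_lod_qc"] = bool(pooled < LOD_QC_MAX_PCT) if np.isfinite(pooled) else False
        rows.append(row)
    report = pd.DataFrame(rows).set_index("assay")
    if decisions is not None and len(decisions):
        chosen = decisions.set_index("chosen_assay")["chosen_panel"]
        report["chosen_duplicate"] = report.index.map(chosen)
    return report


@dataclass
class PreprocessResult:
    matrix: pd.DataFrame           # standardized, one column per protein
    decisions: pd.DataFrame        # duplicate-resolution choices
    qc: pd.DataFrame               # per-assay QC table


def preprocess_study(matrix, lod_mask, annotations, subjects) -> PreprocessResult:
    """LOD substitution -> duplicate resolution -> within-cohort standardization."""
    qc = qc_report(lod_mask, annotations, subjects)
    sub = substitute_lod(matrix, lod_mask, annotations)
    resolved, decisions = resolve_duplicates(sub, annotations, subjects)
    std = standardize_within_cohort(resolved, subjects)
    if len(decisions):
        qc = qc_report(lod_mask, annotations, subjects, decisions)
    return PreprocessResult(matrix=std, decisions=decisions, qc=qc)
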