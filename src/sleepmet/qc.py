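"""Metabolite exclusion rules and missing-value policy for targeted panels.

A metabolite is excluded when any of the following holds (strict
inequalities): more than 25% of study-sample measurements are below LOD,
below LLOQ, or above ULOQ; the mean blank signal exceeds the LOD ("blank out
of range"); or the coefficient of variation over QC level-2 replicates
exceeds 30%. Fractions are computed over study samples only. Rules that need
QC or blank rows degrade gracefully (skipped with a warning) when those rows
are absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .panel import ABOVE_ULOQ, BELOW_LLOQ, BELOW_LOD, PanelManifest, SampleTable, StudyDesign

REASONS = ("pct_below_lod", "pct_below_lloq", "pct_above_uloq", "blank_out_of_range", "qc2_cv")


class QcError(ValueError):
    pass


def percent_cv(values) -> float:
    """Percent coefficient of variation: 100 · sample sd (n−1) / mean."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 2:
        raise QcError("percent_cv needs at least 2 non-missing values")
    m = x.mean()
    if m <= 0:
        raise QcError("percent_cv undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / m)


@dataclass
class FilterResult:
    """Partition of the panel into retained and excluded metabolites."""

    retained: list[str]
    excluded: list[tuple[str, list[str]]]  # (metabolite_id, reasons)
    diagnostics: pd.DataFrame  # per-metabolite pct flags and qc2 CV%

    @property
    def excluded_ids(self) -> list[str]:
        return [mid for mid, _ in self.excluded]

    def reasons_for(self, metabolite_id: str) -> list[str]:
        for mid, reasons in self.excluded:
            if mid == metabolite_id:
                return reasons
        return []

    def to_dict(self) -> dict:
        return {
            "n_retained": len(self.retained),
            "n_excluded": len(self.excluded),
            "retained": self.retained,
            "excluded": {mid: reasons for mid, reasons in self.excluded},
        }


def apply_exclusion_rules(
    table: SampleTable,
    manifest: PanelManifest,
    config: PipelineConfig | None = None,
) -> FilterResult:
    """Apply the five panel exclusion rules; every triggered reason is recorded."""
    config = config or PipelineConfig()
    pct_cut = config.pct_flag_cutoff
    cv_cut = config.qc_cv_cutoff

    study_ids = table.study_samples()
    if not study_ids:
        raise QcError("no study samples in table")
    qc2_ids = table.samples_with_role("qc2")
    blank_ids = table.samples_with_role("blank")
    if len(qc2_ids) < 2:
        warnings.warn("fewer than 2 QC2 replicates: QC2 CV rule skipped", stacklevel=2)
    if not blank_ids:
        warnings.warn("no blank rows: blank-out-of-range rule skipped", stacklevel=2)

    status = table.status.loc[study_ids]
    n_study = len(study_ids)
    diag_rows = []
    retained, excluded = [], []
    for mid in table.metabolite_ids:
        col = status[mid]
        pct_lod = 100.0 * (col == BELOW_LOD).sum() / n_study
        pct_lloq = 100.0 * (col == BELOW_LLOQ).sum() / n_study
        pct_uloq = 100.0 * (col == ABOVE_ULOQ).sum() / n_study
        reasons = []
        if pct_lod > pct_cut:
            reasons.append("pct_below_lod")
        if pct_lloq > pct_cut:
            reasons.append("pct_below_lloq")
        if pct_uloq > pct_cut:
            reasons.append("pct_above_uloq")

        blank_mean = np.nan
        if blank_ids:
            blank_mean = float(table.concentrations.loc[blank_ids, mid].mean())
            if blank_mean > manifest.table.at[mid, "lod"]:
                reasons.append("blank_out_of_range")

        cv = np.nan
        if len(qc2_ids) >= 2:
            vals = table.concentrations.loc[qc2_ids, mid].dropna()
            if len(vals) >= 2 and vals.mean() > 0:
                cv = percent_cv(vals)
                if cv > cv_cut:
                    reasons.append("qc2_cv")

        diag_rows.append(
            {
                "metabolite_id": mid,
                "pct_below_lod": pct_lod,
                "pct_below_lloq": pct_lloq,
                "pct_above_uloq": pct_uloq,
                "blank_mean": blank_mean,
                "qc2_cv": cv,
            }
        )
        if reasons:
            excluded.append((mid, reasons))
        else:
            retained.append(mid)

    diagnostics = pd.DataFrame(diag_rows).set_index("metabolite_id")
    return FilterResult(retained, excluded, diagnostics)


def missing_policy_view(
    table: SampleTable,
    design: StudyDesign,
    metabolite_id: str,
) -> tuple[pd.Series, pd.Series, int]:
    """Pairwise-deletion view for one metabolite: (values, group labels, n_dropped).

    Study-sample cells without a valid concentration are dropped; groups that
    lose all their samples are reported with a warning. Raises when fewer than
    two groups keep at least two values.
    """
    conc = table.study_concentrations()[metabolite_id]
    groups = design.table["group"].reindex(conc.index)
    keep = conc.notna()
    n_dropped = int((~keep).sum())
    vals, labels = conc[keep], groups[keep]
    lost = set(groups.unique()) - set(labels.unique())
    if lost:
        warnings.warn(
            f"{metabolite_id}: groups entirely missing and dropped from testing: {sorted(lost)}",
            stacklevel=2,
        )
    sizes = labels.value_counts()
    if (sizes >= 2).sum() < 2:
        raise QcError(f"{metabolite_id}: fewer than 2 groups with >= 2 values remain")
    return vals, labels, n_dropped
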