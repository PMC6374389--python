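"""End-to-end pipeline: filter → chemometrics → group stats → biomarker (+ NMR).

``run_pipeline`` executes the full analysis on provided tables or on a
simulated cohort, writes a report directory (CSV tables, figures, versioned
JSON summary) and is byte-reproducible given the seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker as bm
from . import chemometrics as chem
from . import nmr as nmrmod
from . import stats as gs
from .config import PipelineConfig
from .panel import (
    CONTROL_GROUP,
    CovariateTable,
    PanelManifest,
    SampleTable,
    StudyDesign,
    default_manifest,
)
from .qc import apply_exclusion_rules
from .simulate import SimConfig, simulate_cohort
from .spectra_sim import default_outlier_plan, simulate_spectra

REPORT_SCHEMA_VERSION = "1.0"

log = logging.getLogger("sleepmet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineInputs:
    """Either concrete tables or a directive to simulate them."""

    manifest: PanelManifest | None = None
    table: SampleTable | None = None
    design: StudyDesign | None = None
    covariates: CovariateTable | None = None
    spectra: list | None = None
    simulate: bool = False
    n_per_group: int = 11
    simulate_spectra_n: int = 0


@dataclass
class ReportBundle:
    out_dir: Path
    summary: dict

    @property
    def sections(self) -> list[str]:
        return list(self.summary["sections"].keys())


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _opls_section(
    conc: pd.DataFrame, design: StudyDesign, group_a: str, group_b: str, config: PipelineConfig
) -> dict:
    ids = design.samples_in(group_a) + design.samples_in(group_b)
    ids = [s for s in ids if s in conc.index]
    sub = conc.loc[ids].dropna(axis=1)
    y = np.array([0 if design.group_of(s) == group_a else 1 for s in ids])
    scaled = chem.scale_matrix(np.log(sub.to_numpy()), config.scaling.get("lcms", "uv"))
    model = chem.fit_opls_da(
        scaled.X, y, folds=config.cv_folds, n_perm=config.n_perm_opls, seed=config.seed
    )
    pcorr = pd.Series(model.pcorr, index=sub.columns)
    up = pcorr[pcorr > config.pcorr_cutoff].sort_values(ascending=False)
    down = pcorr[pcorr < -config.pcorr_cutoff].sort_values()
    return {
        "groups": [group_a, group_b],
        "r2x": model.r2x,
        "r2y": model.r2y,
        "q2y": model.q2y,
        "components": model.n_components,
        "cv_anova_p": model.cv_anova_p,
        "permutation_p": model.permutation_p,
        "pcorr_increased": {k: float(v) for k, v in up.items()},
        "pcorr_decreased": {k: float(v) for k, v in down.items()},
    }


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    out_dir: str | Path,
    contrasts: tuple[tuple[str, str], ...] = ((CONTROL_GROUP, "ROT-CT"), (CONTROL_GROUP, "SHAM-SR"), (CONTROL_GROUP, "ROT-SR")),
    make_plots: bool = True,
) -> ReportBundle:
    """Run the full analysis and write a report directory.

    Stages: (1) QC filter, (2) pair-wise OPLS-DA per contrast, (3) six-group
    and two-factor ANOVA with FDR + Ward heat-map ordering + correlation
    screen, (4) stepwise LOOCV biomarker model for the SR contrast, (5) the
    NMR branch when spectra are given. Any stage failure aborts with the
    stage name in the exception and log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    sections: dict = {}

    stage = "inputs"
    try:
        manifest = inputs.manifest or default_manifest()
        if inputs.simulate:
            sim = SimConfig(manifest=manifest, n_per_group=inputs.n_per_group, seed=config.seed)
            table, design, covs = simulate_cohort(sim)
            spectra = (
                simulate_spectra(
                    inputs.simulate_spectra_n,
                    default_outlier_plan(inputs.simulate_spectra_n),
                    seed=config.seed,
                )
                if inputs.simulate_spectra_n
                else None
            )
        else:
            table, design, covs, spectra = inputs.table, inputs.design, inputs.covariates, inputs.spectra
        if table is None or design is None:
            raise ValueError("sample table and study design are required")
        if not table.study_samples():
            raise ValueError("no study samples")
        table.write_csv(out / "sample_table.csv")
        design.write_csv(out / "design.csv")

        stage = "filter"
        log.info("stage filter")
        filt = apply_exclusion_rules(table, manifest, config)
        with open(out / "filter_report.json", "w", encoding="utf-8") as fh:
            json.dump(_round_floats(filt.to_dict()), fh, indent=1, sort_keys=True)
        retained = table.subset_metabolites(filt.retained)
        sections["filter"] = {
            "n_retained": len(filt.retained),
            "n_excluded": len(filt.excluded),
            "retained_by_class": manifest.counts_by_class(filt.retained),
        }

        stage = "chemometrics"
        log.info("stage chemometrics")
        conc = retained.study_concentrations()
        opls_out = {}
        for ga, gb in contrasts:
            if design.samples_in(ga) and design.samples_in(gb):
                opls_out[f"{ga}_vs_{gb}"] = _opls_section(conc, design, ga, gb, config)
        sections["opls"] = opls_out

        stage = "group_stats"
        log.info("stage group_stats")
        stats_res = gs.compute_group_stats(retained, design, config)
        stats_res.ratios.to_csv(out / "ratios.csv")
        stats_res.tests.to_csv(out / "tests.csv")
        dend = gs.ward_cluster(
            np.log(conc).apply(lambda c: (c - c.mean()) / (c.std() or 1.0)),
            axis=1,
            labels=list(conc.columns),
        )
        hits = gs.correlation_screen(conc, covs, config.r_cutoff) if covs is not None else []
        pd.DataFrame([h.__dict__ for h in hits]).to_csv(out / "correlation_hits.csv", index=False)
        sections["group_stats"] = {
            "n_significant_oneway": len(stats_res.significant("q_oneway", config.fdr_cutoff)),
            "significant_oneway": stats_res.significant("q_oneway", config.fdr_cutoff),
            "heatmap_leaf_order": dend.ordered_labels[:20],
            "n_correlation_hits": len(hits),
            "top_correlations": [
                {"a": h.entity_a, "b": h.entity_b, "r": h.pearson_r} for h in hits[:10]
            ],
        }

        stage = "biomarker"
        log.info("stage biomarker")
        sr_ids = [s for s in conc.index if design.table.at[s, "procedure"] == "SR"]
        ct_ids = [s for s in conc.index if design.table.at[s, "procedure"] == "CT"]
        labels = pd.Series(
            [1 if s in sr_ids else 0 for s in ct_ids + sr_ids], index=ct_ids + sr_ids
        )
        sub_conc = conc.loc[ct_ids + sr_ids]
        cand = bm.select_candidates(stats_res.tests["q_sr"], sub_conc, labels, config)
        model = bm.stepwise_select(cand, sub_conc, labels, config)
        with open(out / "biomarker_model.json", "w", encoding="utf-8") as fh:
            json.dump(_round_floats(model.to_dict()), fh, indent=1, sort_keys=True)
        sections["biomarker"] = {
            "n_candidates": len(cand.members),
            "selected": model.selected,
            "loocv_auc": model.final_auc if model.selected else None,
            "metrics": {k: v for k, v in model.metrics.items()},
        }

        stage = "nmr"
        if spectra:
            log.info("stage nmr")
            kept, flagged, notes = nmrmod.preprocess_spectra(spectra)
            sections["nmr"] = {
                "n_spectra": len(spectra),
                "n_outliers_removed": len(flagged),
                "outliers": notes,
            }
            with open(out / "nmr_outliers.json", "w", encoding="utf-8") as fh:
                json.dump(notes, fh, indent=1, sort_keys=True)
        else:
            sections["nmr"] = {"n_spectra": 0, "skipped": True}

        if make_plots:
            stage = "figures"
            _write_figures(out, stats_res, opls_out, model)
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc

    summary = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "sections": sections,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_round_floats(summary), fh, indent=1, sort_keys=True)
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return ReportBundle(out, summary)


def _write_figures(out: Path, stats_res, opls_out: dict, model) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if opls_out:
        name, sec = next(iter(opls_out.items()))
        fig, ax = plt.subplots(figsize=(6, 3))
        items = list(sec["pcorr_increased"].items())[:15] + list(sec["pcorr_decreased"].items())[:15]
        if items:
            ax.bar([k for k, _ in items], [v for _, v in items])
            ax.set_ylabel("p(corr)")
            ax.tick_params(axis="x", rotation=90, labelsize=5)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(out / "pcorr.png", dpi=100)
        plt.close(fig)
    if model.roc is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(model.roc[:, 0], model.roc[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC ({'+'.join(model.selected)})")
        fig.tight_layout()
        fig.savefig(out / "roc.png", dpi=100)
        plt.close(fig)
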