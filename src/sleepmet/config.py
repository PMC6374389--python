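"""Pipeline configuration container with the analysis defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and settings shared across the pipeline stages.

    Defaults follow the study conventions: FDR cutoff 0.05, |p(corr)| 0.3,
    correlation screen |r| 0.4, 10,000 permutations for the AUC null, 999 for
    OPLS-DA validation, 7-fold cross-validation, 50% classification threshold,
    5% minimum concentration difference for biomarker candidates.
    """

    seed: int = 0
    fdr_cutoff: float = 0.05
    pcorr_cutoff: float = 0.3
    r_cutoff: float = 0.4
    n_perm_auc: int = 10000
    n_perm_opls: int = 999
    cv_folds: int = 7
    prob_threshold: float = 0.5
    min_pct_diff: float = 5.0
    #: scaling per platform: unit-variance for targeted LC/MS, Pareto for NMR
    scaling: dict = field(default_factory=lambda: {"lcms": "uv", "nmr": "pareto"})
    #: QC-filter thresholds (strict inequalities)
    pct_flag_cutoff: float = 25.0
    qc_cv_cutoff: float = 30.0
    #: ANOVA on log concentrations by default
    log_transform: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fdr_cutoff < 1 and 0 < self.prob_threshold < 1):
            raise ValueError("fdr_cutoff and prob_threshold must lie in (0,1)")
        if not (0 <= self.pcorr_cutoff <= 1 and 0 <= self.r_cutoff <= 1):
            raise ValueError("pcorr_cutoff and r_cutoff must lie in [0,1]")
        if self.n_perm_auc < 99 or self.n_perm_opls < 99:
            raise ValueError("permutation counts must be >= 99")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.min_pct_diff < 0:
            raise ValueError("min_pct_diff must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
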