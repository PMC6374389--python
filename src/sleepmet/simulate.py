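"""Synthetic cohort generator for the sleep-restriction × rotenone design.

Generates targeted-panel concentration tables with the statistical structure
the downstream analysis assumes: group-specific multiplicative effects on a
log-normal noise model, cross-metabolite and metabolite–covariate
correlations realized on the log scale within group, optional LOD censoring,
three-level QC replicates and blanks, and a deterministic QC-violation
fixture whose retained set has a prescribed class composition.

The default effect table encodes the published group-mean ratios for the ten
metabolites with significant six-group differences, ±15% for metabolites
reported only by direction of change, 1.00 elsewhere, and 1.00 for the
rebound groups (where the sleep-restriction and rotenone effects were lost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (
    BELOW_LOD,
    BELOW_LLOQ,
    CONTROL_GROUP,
    GROUPS,
    CovariateTable,
    PanelManifest,
    SampleTable,
    StudyDesign,
    default_baselines,
    flag_concentrations,
)

ACTIVITY = "total_activity"
SLEEP = "sleep_condition"

# ---------------------------------------------------------------------------
# effect table

# group-mean concentration ratios vs SHAM-CT (order SHAM-CT, SHAM-SR, ROT-CT,
# ROT-SR); rebound groups default to 1.00
_TABLE1_RATIOS = {
    "Ile": (1.00, 1.22, 1.12, 1.35),
    "Leu": (1.00, 1.26, 1.18, 1.40),
    "Val": (1.00, 1.21, 1.12, 1.33),
    "alpha-AAA": (1.00, 0.87, 0.72, 0.92),
    "Kynurenine": (1.00, 0.79, 1.15, 0.72),
    "PC aa C30:0": (1.00, 1.19, 1.17, 1.36),
    "PC aa C34:1": (1.00, 1.21, 1.17, 1.43),
    "PC aa C40:2": (1.00, 1.02, 1.13, 1.48),
    "PC aa C42:4": (1.00, 1.01, 1.00, 1.26),
    "PC ae C38:3": (1.00, 1.10, 1.27, 1.49),
}

#: default magnitude for metabolites reported only by direction of change
DEFAULT_EFFECT = 0.15

# direction-of-change lists per comparison group (metabolites not already in
# the ratio table above); +1 increased, -1 decreased vs SHAM-CT
_DIRECTIONS = {
    "ROT-CT": {"Orn": +1, "C3": -1},
    "SHAM-SR": {
        "Orn": +1, "Arg": +1, "Lys": +1, "Ala": +1, "Pro": +1, "Phe": +1, "C0": +1,
        "Creatinine": -1, "Putrescine": -1, "SDMA": -1, "OH-Pro": -1,
        "C2": -1, "C14:1": -1, "C5:1-DC": -1,
    },
    "ROT-SR": {
        "Orn": +1, "Arg": +1, "Lys": +1, "Pro": +1, "Phe": +1, "Ser": +1,
        "Spermidine": +1, "SM C16:1": +1,
        "Creatinine": -1, "OH-Pro": -1, "C2": -1, "C14:1": -1,
    },
}


@dataclass
class EffectTable:
    """Multiplicative group-mean ratio vs SHAM-CT per metabolite × group."""

    table: pd.DataFrame  # index metabolite_id, columns GROUPS

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(GROUPS):
            raise ValueError(f"effect table columns must be {GROUPS}")
        if not np.allclose(self.table[CONTROL_GROUP], 1.0):
            raise ValueError("SHAM-CT ratio must be 1.00 for every metabolite")
        if (self.table.values <= 0).any():
            raise ValueError("ratios must be > 0")

    def ratio(self, metabolite_id: str, group: str) -> float:
        return float(self.table.at[metabolite_id, group])


def default_effect_table(manifest: PanelManifest) -> EffectTable:
    """Effect table with published ratios, ±15% direction-only defaults, else 1."""
    df = pd.DataFrame(1.0, index=pd.Index(manifest.ids, name="metabolite_id"), columns=list(GROUPS))
    for mid, (ct, sr, rct, rsr) in _TABLE1_RATIOS.items():
        if mid in df.index:
            df.loc[mid, ["SHAM-CT", "SHAM-SR", "ROT-CT", "ROT-SR"]] = [ct, sr, rct, rsr]
    for grp, dirs in _DIRECTIONS.items():
        for mid, sign in dirs.items():
            if mid in df.index and df.at[mid, grp] == 1.0:
                df.at[mid, grp] = 1.0 + sign * DEFAULT_EFFECT
    return EffectTable(df)


# ---------------------------------------------------------------------------
# correlation spec and PSD completion


@dataclass
class CorrelationSpec:
    """Target Pearson correlations between metabolites and/or covariates.

    Pairs involving ``sleep_condition`` are realized through the group
    structure (sleep_condition is constant within a group); all other pairs
    are realized on the log scale within group by a joint Gaussian.
    """

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for a, b, r in self.pairs:
            if not -1 < r < 1:
                raise ValueError(f"target r for ({a},{b}) must lie in (-1,1), got {r}")

    def within_group_pairs(self) -> list[tuple[str, str, float]]:
        return [(a, b, r) for a, b, r in self.pairs if SLEEP not in (a, b)]

    def sleep_pairs(self) -> list[tuple[str, str, float]]:
        return [(a, b, r) for a, b, r in self.pairs if SLEEP in (a, b)]


def default_correlation_spec() -> CorrelationSpec:
    """The default correlation targets (BCAA block, aromatic/Met block, activity)."""
    return CorrelationSpec(
        [
            (ACTIVITY, SLEEP, -0.57),
            (ACTIVITY, "Met", 0.41),
            ("Leu", "Ile", 0.90),
            ("Val", "Ile", 0.94),
            ("Val", "Leu", 0.89),
            ("Phe", "Met", 0.73),
            ("Trp", "Met", 0.64),
        ]
    )


def complete_correlation(
    entities: list[str],
    pairs: list[tuple[str, str, float]],
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> np.ndarray:
    """PSD completion of a partially specified correlation matrix.

    Unspecified off-diagonal entries are free; alternating projections between
    the PSD cone and the affine set (specified entries + unit diagonal) find a
    positive semi-definite completion that keeps the specified correlations
    exact. Raises if the targets admit no PSD completion.
    """
    n = len(entities)
    idx = {e: i for i, e in enumerate(entities)}
    target = np.eye(n)
    mask = np.zeros((n, n), dtype=bool)
    for a, b, r in pairs:
        i, j = idx[a], idx[b]
        target[i, j] = target[j, i] = r
        mask[i, j] = mask[j, i] = True
    x = target.copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(x)
        x = (v * np.clip(w, tol, None)) @ v.T
        x[mask] = target[mask]
        np.fill_diagonal(x, 1.0)
        if np.linalg.eigvalsh(x).min() > -1e-10:
            break
    if np.linalg.eigvalsh(x).min() < -1e-8:
        raise ValueError("infeasible correlation spec: no PSD completion found")
    return x


# ---------------------------------------------------------------------------
# simulation config


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the study: ~11 animals per group, log-normal noise with
    log-scale sd 0.15 per metabolite, the published effect ratios, the default
    correlation targets, activity recorded in seconds per day.
    """

    manifest: PanelManifest
    n_per_group: int = 11
    baselines: pd.Series | None = None  # µM means for SHAM-CT
    log_sd: float | pd.Series = 0.15
    effects: EffectTable | None = None
    correlations: CorrelationSpec | None = None
    lod_censor: bool = False
    qc_replicates: int = 4
    qc_cv: dict = field(default_factory=lambda: {"qc1": 10.0, "qc2": 10.0, "qc3": 10.0})
    n_blanks: int = 3
    activity_mean: float = 5400.0  # seconds of activity on the day killed
    activity_sd: float = 900.0  # within-group sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.baselines is None:
            self.baselines = default_baselines(self.manifest)
        if self.effects is None:
            self.effects = default_effect_table(self.manifest)
        if self.correlations is None:
            self.correlations = default_correlation_spec()
        sds = self.log_sd_series()
        if (sds <= 0).any():
            raise ValueError("log-scale sds must be > 0")

    def log_sd_series(self) -> pd.Series:
        if np.isscalar(self.log_sd):
            return pd.Series(float(self.log_sd), index=self.manifest.ids)
        return pd.Series(self.log_sd).reindex(self.manifest.ids)


# ---------------------------------------------------------------------------
# cohort simulation


def _sample_correlated_noise(
    rng: np.random.Generator,
    n: int,
    mets: list[str],
    log_sds: pd.Series,
    spec: CorrelationSpec,
    activity_sd: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Within-group noise: log-scale metabolite deviations + activity deviation."""
    wg = spec.within_group_pairs()
    corr_entities = sorted({e for a, b, _ in wg for e in (a, b)})
    missing = [e for e in corr_entities if e != ACTIVITY and e not in mets]
    if missing:
        raise ValueError(f"correlation spec names unknown metabolites: {missing}")
    eps = pd.DataFrame(
        rng.standard_normal((n, len(mets))) * log_sds.to_numpy()[None, :],
        columns=mets,
    )
    act = rng.standard_normal(n) * activity_sd
    if corr_entities:
        corr = complete_correlation(corr_entities, wg)
        # Cholesky with small jitter for the PSD-boundary case
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr_entities)))
        z = rng.standard_normal((n, len(corr_entities))) @ chol.T
        for k, e in enumerate(corr_entities):
            if e == ACTIVITY:
                act = z[:, k] * activity_sd
            else:
                eps[e] = z[:, k] * log_sds[e]
    return eps, act


def simulate_cohort(cfg: SimConfig) -> tuple[SampleTable, StudyDesign, CovariateTable]:
    """Draw a full study cohort (study samples + QC replicates + blanks).

    Concentrations follow log x = log(baseline · ratio[group]) + ε with ε a
    correlated within-group Gaussian realizing the correlation spec. The
    activity covariate is wired into the same structure, with a sleep-condition
    deficit calibrated so the pooled point-biserial correlation matches the
    sleep-pair target.
    """
    rng = np.random.default_rng(cfg.seed)
    mets = cfg.manifest.ids
    log_sds = cfg.log_sd_series()
    base = cfg.baselines.reindex(mets)

    # pooled point-biserial target r: activity deficit d = sd·|r|/sqrt((1-r²)pq)
    sleep_target = dict(
        ((a, b) if a <= b else (b, a), r) for a, b, r in cfg.correlations.sleep_pairs()
    )
    r_sleep = sleep_target.get(tuple(sorted((ACTIVITY, SLEEP))), -0.57)
    p_sr = 1.0 / 3.0  # fraction of SR samples in the balanced six-group design
    pq = p_sr * (1 - p_sr)
    act_delta = cfg.activity_sd * abs(r_sleep) / np.sqrt((1 - r_sleep**2) * pq)

    frames, design_rows, cov_rows = [], [], []
    for g in GROUPS:
        treatment, procedure = g.split("-")
        sleep = 1 if procedure == "SR" else 0
        eps, act_noise = _sample_correlated_noise(
            rng, cfg.n_per_group, mets, log_sds, cfg.correlations, cfg.activity_sd
        )
        ratios = cfg.effects.table.loc[mets, g].to_numpy()
        logx = np.log(base.to_numpy() * ratios)[None, :] + eps.to_numpy()
        ids = [f"{g}_{i + 1:02d}" for i in range(cfg.n_per_group)]
        frames.append(pd.DataFrame(np.exp(logx), index=ids, columns=mets))
        for k, sid in enumerate(ids):
            design_rows.append({"sample_id": sid, "treatment": treatment, "procedure": procedure})
            cov_rows.append(
                {
                    "sample_id": sid,
                    ACTIVITY: cfg.activity_mean - act_delta * sleep + act_noise[k],
                    SLEEP: sleep,
                }
            )

    conc = pd.concat(frames)
    roles = pd.Series("study", index=conc.index)
    study = _to_sample_table(conc, roles, cfg)

    qc = simulate_qc_and_blanks(cfg)
    table = SampleTable(
        pd.concat([study.concentrations, qc.concentrations]),
        pd.concat([study.status, qc.status]),
        pd.concat([study.roles, qc.roles]),
    )
    design = StudyDesign(pd.DataFrame(design_rows).set_index("sample_id"))
    covs = CovariateTable(pd.DataFrame(cov_rows).set_index("sample_id"))
    return table, design, covs


def _to_sample_table(conc: pd.DataFrame, roles: pd.Series, cfg: SimConfig) -> SampleTable:
    # flags always reflect the manifest bounds; censoring controls whether
    # the sub-LOD reading itself is reported or removed
    status = flag_concentrations(conc, cfg.manifest)
    if cfg.lod_censor:
        conc = conc.mask(status == BELOW_LOD)
    return SampleTable(conc, status, roles)


# QC level expected values as multiples of the study baseline
_QC_LEVEL_FACTOR = {"qc1": 0.5, "qc2": 1.0, "qc3": 2.0}


def simulate_qc_and_blanks(cfg: SimConfig) -> SampleTable:
    """QC replicate rows (three levels, configurable CV%) and near-zero blanks."""
    if cfg.qc_replicates < 2:
        raise ValueError("need >= 2 QC replicates per level")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9C]))
    mets = cfg.manifest.ids
    base = cfg.baselines.reindex(mets).to_numpy()
    lod = cfg.manifest.table["lod"].to_numpy()

    rows, roles, ids = [], [], []
    for level in ("qc1", "qc2", "qc3"):
        expected = base * _QC_LEVEL_FACTOR[level]
        cv = float(cfg.qc_cv.get(level, 10.0)) / 100.0
        for rep in range(cfg.qc_replicates):
            noise = rng.standard_normal(len(mets)) * cv if cv > 0 else 0.0
            vals = np.maximum(expected * (1.0 + noise), 1e-9)
            rows.append(vals)
            roles.append(level)
            ids.append(f"{level.upper()}_{rep + 1:02d}")
    for b in range(cfg.n_blanks):
        rows.append(lod * rng.uniform(0.05, 0.5, size=len(mets)))
        roles.append("blank")
        ids.append(f"BLANK_{b + 1:02d}")

    conc = pd.DataFrame(np.asarray(rows), index=ids, columns=mets)
    return _to_sample_table(conc, pd.Series(roles, index=ids), cfg)


# ---------------------------------------------------------------------------
# deterministic QC-violation fixture


@dataclass
class QcViolationFixture:
    """A cohort with engineered QC violations plus the ledger describing them."""

    table: SampleTable
    ledger: dict[str, list[str]]  # reason -> metabolite ids

    @property
    def n_violations(self) -> int:
        return sum(len(v) for v in self.ledger.values())


# per-class allocation of the engineered violations over the five rules,
# chosen so the retained panel has composition 10/21/12/76/14
_VIOLATION_ALLOCATION = {
    "acylcarnitine": {"pct_below_lod": 10, "pct_below_lloq": 6, "pct_above_uloq": 4, "blank_out_of_range": 4, "qc2_cv": 6},
    "biogenic_amine": {"pct_below_lod": 2, "pct_below_lloq": 1, "pct_above_uloq": 1, "blank_out_of_range": 1, "qc2_cv": 2},
    "glycerophospholipid": {"pct_below_lod": 4, "pct_below_lloq": 3, "pct_above_uloq": 2, "blank_out_of_range": 2, "qc2_cv": 2},
}

# fixed multiplicative pattern for QC2 replicates of CV-violating metabolites
# (sample CV ≈ 42% > 30%)
_HIGH_CV_PATTERN = np.array([0.4, 0.7, 1.0, 1.0, 1.3, 1.6])


def make_qc_violation_fixture(
    manifest: PanelManifest, seed: int = 0, violate: bool = True
) -> QcViolationFixture:
    """Deterministic fixture in which 50 designated metabolites each violate
    exactly one exclusion rule (30 acylcarnitines, 7 biogenic amines, 13
    glycerophospholipids), so the retained set has the published composition.

    With ``violate=False`` the clean variant is returned (nothing excluded).
    """
    if len(manifest) != 183:
        raise ValueError(f"fixture requires the packaged 183-entry manifest, got {len(manifest)}")
    cfg = SimConfig(
        manifest=manifest,
        n_per_group=4,  # 24 study samples
        log_sd=0.1,
        qc_replicates=len(_HIGH_CV_PATTERN),
        qc_cv={"qc1": 5.0, "qc2": 5.0, "qc3": 5.0},
        seed=seed,
        lod_censor=True,
    )
    table, _, _ = simulate_cohort(cfg)
    ledger: dict[str, list[str]] = {
        k: [] for k in ("pct_below_lod", "pct_below_lloq", "pct_above_uloq", "blank_out_of_range", "qc2_cv")
    }
    if not violate:
        return QcViolationFixture(table, ledger)

    conc, status = table.concentrations.copy(), table.status.copy()
    study_ids = table.study_samples()
    n_hit = int(np.floor(len(study_ids) * 0.25)) + 3  # comfortably > 25% of study cells
    qc2_ids = table.samples_with_role("qc2")
    blank_ids = table.samples_with_role("blank")

    for cls, alloc in _VIOLATION_ALLOCATION.items():
        cls_mets = [m for m in manifest.ids if manifest.class_of(m) == cls]
        pos = 0
        for reason, count in alloc.items():
            for mid in cls_mets[pos : pos + count]:
                row = manifest.table.loc[mid]
                if reason == "pct_below_lod":
                    conc.loc[study_ids[:n_hit], mid] = 0.5 * row["lod"]
                    status.loc[study_ids[:n_hit], mid] = BELOW_LOD
                elif reason == "pct_below_lloq":
                    conc.loc[study_ids[:n_hit], mid] = 0.8 * row["lloq"]
                    status.loc[study_ids[:n_hit], mid] = BELOW_LLOQ
                elif reason == "pct_above_uloq":
                    conc.loc[study_ids[:n_hit], mid] = 1.5 * row["uloq"]
                    status.loc[study_ids[:n_hit], mid] = "above_uloq"
                elif reason == "blank_out_of_range":
                    conc.loc[blank_ids, mid] = 2.0 * row["lod"]
                    status.loc[blank_ids, mid] = BELOW_LLOQ  # above LOD, below LLOQ
                elif reason == "qc2_cv":
                    expected = float(cfg.baselines[mid]) * _QC_LEVEL_FACTOR["qc2"]
                    conc.loc[qc2_ids, mid] = expected * _HIGH_CV_PATTERN[: len(qc2_ids)]
                ledger[reason].append(mid)
            pos += count
    return QcViolationFixture(SampleTable(conc, status, table.roles.copy()), ledger)
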