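"""Per-metabolite group statistics, FDR control, clustering and correlations.

Provides ratio-to-control tables, one-way (six-group) ANOVA and two-factor
(treatment × procedure) linear models on log concentrations, Benjamini–
Hochberg FDR across metabolites (one family per test type), Ward clustering
for heat-map ordering, and the |r| > 0.4 correlation screen over metabolite
and covariate pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .panel import CONTROL_GROUP, GROUPS, CovariateTable, SampleTable, StudyDesign


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ratios


def ratios_to_control(
    table: SampleTable, design: StudyDesign, control_group: str = CONTROL_GROUP
) -> pd.DataFrame:
    """Arithmetic group mean / control group mean, per metabolite × group."""
    conc = table.study_concentrations()
    groups = design.table["group"].reindex(conc.index)
    means = conc.groupby(groups).mean()
    if control_group not in means.index:
        raise StatsError(f"control group {control_group} absent")
    ctrl = means.loc[control_group]
    if (ctrl <= 0).any():
        bad = list(ctrl.index[ctrl <= 0])
        raise StatsError(f"control mean <= 0 for {bad}")
    return (means / ctrl).T  # metabolites × groups


# ---------------------------------------------------------------------------
# ANOVA


def one_way_anova(values, groups) -> float:
    """Classical one-way ANOVA F-test p-value."""
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups))
    arrays = [values[groups == g].to_numpy() for g in groups.unique()]
    arrays = [a for a in arrays if len(a) >= 2]
    if len(arrays) < 2:
        raise StatsError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 1.0
    f, p = sps.f_oneway(*arrays)
    return float(p)


def two_factor_anova(values, treatment, procedure) -> tuple[float, float, float]:
    """Two-way linear model, Type-II sums of squares.

    Returns (p_treatment, p_procedure, p_interaction); the interaction is
    tested only when the full-factorial design permits (NaN otherwise).
    Constant responses return p = 1 for every term.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "t": treatment, "pr": procedure})
    df = df.dropna()
    if df["t"].nunique() < 2 or df["pr"].nunique() < 2:
        raise StatsError("both factors must vary")
    if np.ptp(df["y"]) == 0:
        return 1.0, 1.0, 1.0
    cells = df.groupby(["t", "pr"]).size()
    full_factorial = len(cells) == df["t"].nunique() * df["pr"].nunique() and (cells >= 2).all()
    formula = "y ~ C(t) * C(pr)" if full_factorial else "y ~ C(t) + C(pr)"
    fit = ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise StatsError("no residual degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(fit, typ=2)
    p_t = float(tab.loc["C(t)", "PR(>F)"])
    p_p = float(tab.loc["C(pr)", "PR(>F)"])
    p_i = float(tab.loc["C(t):C(pr)", "PR(>F)"]) if full_factorial else float("nan")
    return p_t, p_p, p_i


def two_factor_contrasts(values, treatment, procedure) -> dict[str, float]:
    """Coefficient p-values from the additive model y ~ treatment + procedure.

    Returns p-values for the rotenone-vs-sham, SR-vs-CT and REB-vs-CT
    contrasts — the per-column comparisons of the published ratio table.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "t": treatment, "pr": procedure}).dropna()
    if np.ptp(df["y"]) == 0:
        return {"rotenone": 1.0, "sr": 1.0, "reb": 1.0}
    fit = ols(
        "y ~ C(t, Treatment('SHAM')) + C(pr, Treatment('CT'))", data=df
    ).fit()
    pv = fit.pvalues
    out = {"rotenone": float("nan"), "sr": float("nan"), "reb": float("nan")}
    for name, p in pv.items():
        if "T.ROT" in name:
            out["rotenone"] = float(p)
        elif "T.SR" in name:
            out["sr"] = float(p)
        elif "T.REB" in name:
            out["reb"] = float(p)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (capped at 1, stable for ties)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise StatsError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# combined stats table


@dataclass
class StatsResult:
    """Per-metabolite ratios, p-values and q-values for every test family."""

    ratios: pd.DataFrame  # metabolites × groups
    tests: pd.DataFrame  # metabolites × (p_/q_ columns)

    def significant(self, column: str, cutoff: float = 0.05) -> list[str]:
        q = self.tests[column]
        return list(q.index[q < cutoff])


def _design_matrices(treatment: pd.Series, procedure: pd.Series) -> dict[str, np.ndarray]:
    """Treatment-coded design matrices for the additive and interaction models."""
    t = (treatment == "ROT").to_numpy(dtype=float)
    sr = (procedure == "SR").to_numpy(dtype=float)
    reb = (procedure == "REB").to_numpy(dtype=float)
    one = np.ones_like(t)
    X_add = np.column_stack([one, t, sr, reb])
    X_full = np.column_stack([one, t, sr, reb, t * sr, t * reb])
    X_t = np.column_stack([one, t])  # treatment only
    X_p = np.column_stack([one, sr, reb])  # procedure only
    return {"add": X_add, "full": X_full, "t": X_t, "p": X_p}


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y after projection on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    r = Y - X @ beta
    return (r**2).sum(axis=0)


def _batch_two_factor(Y: np.ndarray, treatment: pd.Series, procedure: pd.Series) -> dict[str, np.ndarray]:
    """Vectorized Type-II two-way ANOVA + additive-model contrast t-tests.

    Equivalent to :func:`two_factor_anova` / :func:`two_factor_contrasts`
    column by column (checked in the test suite); used when no cells are
    missing, so the design matrix is shared by all metabolites.
    """
    dm = _design_matrices(treatment, procedure)
    n, m = Y.shape
    rss_full, rss_add = _rss(dm["full"], Y), _rss(dm["add"], Y)
    rss_t, rss_p = _rss(dm["t"], Y), _rss(dm["p"], Y)
    df_resid = n - dm["full"].shape[1]
    mse = rss_full / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f_t = (rss_p - rss_add) / 1 / mse
        f_p = (rss_t - rss_add) / 2 / mse
        f_i = (rss_add - rss_full) / 2 / mse
        out = {
            "p_treatment": sps.f.sf(f_t, 1, df_resid),
            "p_procedure": sps.f.sf(f_p, 2, df_resid),
            "p_interaction": sps.f.sf(f_i, 2, df_resid),
        }
    # additive-model coefficient t-tests (rotenone, SR, REB vs control levels)
    X = dm["add"]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    df_add = n - X.shape[1]
    sigma2 = _rss(X, Y) / df_add
    for j, name in ((1, "p_rot"), (2, "p_sr"), (3, "p_reb")):
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[j] / np.sqrt(sigma2 * xtx_inv[j, j])
            out[name] = 2 * sps.t.sf(np.abs(tstat), df_add)
    const = np.ptp(Y, axis=0) == 0
    for k in out:
        out[k] = np.where(const, 1.0, out[k])
    return out


def _batch_oneway(Y: np.ndarray, groups: pd.Series) -> np.ndarray:
    """Vectorized one-way ANOVA p-values (equivalent to scipy f_oneway)."""
    labels = groups.to_numpy()
    uniq = pd.unique(labels)
    n, m = Y.shape
    grand = Y.mean(axis=0)
    ssb = np.zeros(m)
    ssw = np.zeros(m)
    for g in uniq:
        sel = labels == g
        gm = Y[sel].mean(axis=0)
        ssb += sel.sum() * (gm - grand) ** 2
        ssw += ((Y[sel] - gm) ** 2).sum(axis=0)
    df_b, df_w = len(uniq) - 1, n - len(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
        p = sps.f.sf(f, df_b, df_w)
    return np.where(np.ptp(Y, axis=0) == 0, 1.0, p)


def compute_group_stats(
    table: SampleTable,
    design: StudyDesign,
    config: PipelineConfig | None = None,
) -> StatsResult:
    """Run ratios + one-way + two-factor ANOVA with BH-FDR per test family.

    Metabolites without missing cells share one design matrix and go through
    a vectorized path; metabolites with missing values fall back to
    per-metabolite fits under pairwise deletion.
    """
    config = config or PipelineConfig()
    conc = table.study_concentrations()
    groups = design.table["group"].reindex(conc.index)
    treatment = design.table["treatment"].reindex(conc.index)
    procedure = design.table["procedure"].reindex(conc.index)

    ratios = ratios_to_control(table, design)
    complete = list(conc.columns[conc.notna().all()])
    partial = [c for c in conc.columns if c not in complete]

    rows = {}
    if complete:
        Y = conc[complete].to_numpy(dtype=float)
        if config.log_transform:
            Y = np.log(Y)
        batch = _batch_two_factor(Y, treatment, procedure)
        p1 = _batch_oneway(Y, groups)
        for k, mid in enumerate(complete):
            rows[mid] = {
                "p_oneway": p1[k],
                "p_treatment": batch["p_treatment"][k],
                "p_procedure": batch["p_procedure"][k],
                "p_interaction": batch["p_interaction"][k],
                "p_rot": batch["p_rot"][k],
                "p_sr": batch["p_sr"][k],
                "p_reb": batch["p_reb"][k],
            }
    for mid in partial:
        y = conc[mid]
        keep = y.notna()
        yv = np.log(y[keep]) if config.log_transform else y[keep]
        try:
            p1 = one_way_anova(yv, groups[keep])
        except StatsError:
            p1 = np.nan
        try:
            pt, pp, pi = two_factor_anova(yv, treatment[keep], procedure[keep])
        except StatsError:
            pt = pp = pi = np.nan
        contrasts = two_factor_contrasts(yv, treatment[keep], procedure[keep])
        rows[mid] = {
            "p_oneway": p1,
            "p_treatment": pt,
            "p_procedure": pp,
            "p_interaction": pi,
            "p_rot": contrasts["rotenone"],
            "p_sr": contrasts["sr"],
            "p_reb": contrasts["reb"],
        }
    tests = pd.DataFrame(rows).T.reindex(conc.columns)
    for col in list(tests.columns):
        tests[col.replace("p_", "q_")] = bh_fdr(tests[col])
    return StatsResult(ratios, tests)


# ---------------------------------------------------------------------------
# Ward clustering


@dataclass
class Dendrogram:
    """Agglomerative merge history (Ward) plus heat-map leaf order."""

    merges: list[tuple[int, int, float]]  # (node_a, node_b, height)
    leaf_order: list[int]
    labels: list[str]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Recursive traversal visiting the smaller child cluster first."""
    sizes = {i: 1 for i in range(n)}
    children = {}
    for k, (a, b, _, size) in enumerate(Z):
        node = n + k
        children[node] = (int(a), int(b))
        sizes[node] = int(size)

    def visit(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if (sizes[a], a) <= (sizes[b], b) else (b, a)
        return visit(first) + visit(second)

    return visit(n + len(Z) - 1)


def ward_cluster(matrix, axis: int = 0, labels: list[str] | None = None) -> Dendrogram:
    """Ward clustering on Euclidean distances of rows (axis=0) or columns (axis=1).

    Missing cells are mean-imputed per column before clustering.
    """
    X = pd.DataFrame(matrix)
    if axis == 1:
        X = X.T
    if labels is None:
        labels = [str(i) for i in X.index]
    if len(X) < 2:
        raise StatsError("need >= 2 items to cluster")
    X = X.apply(lambda col: col.fillna(col.mean()), axis=0)
    Z = linkage(X.to_numpy(dtype=float), method="ward", metric="euclidean")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return Dendrogram(merges, _leaf_order(Z, len(X)), list(labels))


# ---------------------------------------------------------------------------
# correlation screen


@dataclass
class CorrelationHit:
    entity_a: str
    entity_b: str
    pearson_r: float
    n_pairs: int
    p_value: float
    q_value: float


def correlation_screen(
    metabolite_table: pd.DataFrame,
    covariates: CovariateTable | pd.DataFrame | None = None,
    r_cutoff: float = 0.4,
) -> list[CorrelationHit]:
    """Pearson screen over all metabolite and covariate pairs.

    Binary covariates enter through their 0/1 coding (point-biserial). Hits
    are pairs with |r| strictly above the cutoff; each hit carries a BH-FDR
    adjusted correlation-test p-value over the whole screened family.
    """
    frames = [pd.DataFrame(metabolite_table)]
    if covariates is not None:
        cov = covariates.table if isinstance(covariates, CovariateTable) else pd.DataFrame(covariates)
        frames.append(cov.reindex(frames[0].index))
    data = pd.concat(frames, axis=1).astype(float)
    cols = list(data.columns)

    tested = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = data[[a, b]].dropna()
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                continue
            r, p = sps.pearsonr(pair[a], pair[b])
            tested.append((a, b, float(r), len(pair), float(p)))
    if not tested:
        return []
    qvals = bh_fdr([t[4] for t in tested])
    hits = [
        CorrelationHit(a, b, r, n, p, float(q))
        for (a, b, r, n, p), q in zip(tested, qvals)
        if abs(r) > r_cutoff
    ]
    hits.sort(key=lambda h: -abs(h.pearson_r))
    return hits
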