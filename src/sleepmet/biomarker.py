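"""Logistic biomarker-panel selection with permutation screening and LOOCV.

The procedure mirrors the published prediction-modelling workflow:

1. Candidate screen — a metabolite qualifies when (a) its FDR-adjusted
   group-difference q-value is below 0.05, (b) its single-metabolite
   (non-cross-validated) AUC beats a label-permutation null at P < 0.05, and
   (c) its mean concentration differs by more than 5% between the contrasted
   groups.
2. Panel growth — starting from the empty model, repeatedly add the candidate
   giving the largest leave-one-out cross-validated AUC, as long as the AUC
   strictly improves; logistic models use natural-log concentrations.
3. Reporting — ROC curve of the held-out probabilities and confusion metrics
   at a 50% probability threshold (strictly greater than).

Perfect separation at small n is handled by a tiny ridge penalty (λ = 1e−6)
with a provenance flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig


class BiomarkerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AUC and permutation screen


def auc(scores, labels) -> float:
    """Mann–Whitney AUC (probability form); ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise BiomarkerError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def _rank_auc_matrix(values: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """AUC for many label vectors at once via the rank-sum identity."""
    from scipy.stats import rankdata

    ranks = rankdata(values)  # midranks handle ties
    n1 = label_matrix.sum(axis=1)
    n0 = label_matrix.shape[1] - n1
    rank_sums = label_matrix @ ranks
    return (rank_sums - n1 * (n1 + 1) / 2) / (n1 * n0)


def permutation_auc_pvalue(values, labels, n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for a single metabolite's discriminative AUC.

    The statistic is direction-agnostic, max(AUC, 1−AUC), since markers may
    rise or fall with the condition; p = (1 + #{perm ≥ obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise BiomarkerError("n_perm must be >= 99")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    obs = max(auc(values, labels), 1 - auc(values, labels))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    a = _rank_auc_matrix(values, perms)
    null = np.maximum(a, 1 - a)
    return float((1 + (null >= obs - 1e-12).sum()) / (n_perm + 1))


# ---------------------------------------------------------------------------
# candidate screen


@dataclass
class CandidateSet:
    """Per-metabolite screening flags and diagnostics; members pass all three."""

    flags: pd.DataFrame  # columns fdr_pass, perm_auc_pass, pct_diff_pass + diagnostics

    @property
    def members(self) -> list[str]:
        f = self.flags
        ok = f["fdr_pass"] & f["perm_auc_pass"] & f["pct_diff_pass"]
        return list(f.index[ok])


def select_candidates(
    q_values: pd.Series,
    conc: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> CandidateSet:
    """Screen metabolites by FDR, permutation AUC and % concentration difference.

    ``conc`` holds raw concentrations (samples × metabolites) of the two
    contrasted groups; ``labels`` is the 0/1 class per sample; ``q_values``
    the FDR-adjusted p-values for the relevant comparison.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    rows = {}
    for k, mid in enumerate(conc.columns):
        y = conc[mid]
        keep = y.notna()
        vals, lab = y[keep].to_numpy(), labels[keep].to_numpy().astype(int)
        q = float(q_values.get(mid, np.nan))
        fdr_pass = bool(q < config.fdr_cutoff)
        mean1, mean0 = vals[lab == 1].mean(), vals[lab == 0].mean()
        ratio = mean1 / mean0 if mean0 > 0 else np.nan
        pct_diff = abs(ratio - 1.0) * 100.0 if np.isfinite(ratio) else np.nan
        pct_pass = bool(np.isfinite(pct_diff) and pct_diff > config.min_pct_diff)
        perm_p, raw_auc = np.nan, np.nan
        if fdr_pass and pct_pass and len(np.unique(lab)) == 2:
            # permutation screen only where the cheap criteria already hold
            raw_auc = auc(vals, lab)
            perm_p = permutation_auc_pvalue(
                vals, lab, config.n_perm_auc, seed=(seed + 7919 * (k + 1)) % 2**31
            )
        perm_pass = bool(np.isfinite(perm_p) and perm_p < 0.05)
        rows[mid] = {
            "fdr_pass": fdr_pass,
            "perm_auc_pass": perm_pass,
            "pct_diff_pass": pct_pass,
            "q_value": q,
            "auc": raw_auc,
            "perm_p": perm_p,
            "pct_diff": pct_diff,
        }
    return CandidateSet(pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# logistic regression (IRLS with ridge fallback)


def fit_logistic(
    X, labels, max_iter: int = 100, tol: float = 1e-10, beta0: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` holds the predictors (log concentrations by convention; the
    intercept is added here). Returns (coefficients, ridge_flag); on
    non-convergence or separation the fit falls back to a small ridge penalty
    (λ = 1e−6) and sets the flag.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])

    def irls(lam: float) -> tuple[np.ndarray, bool]:
        beta = np.zeros(A.shape[1]) if beta0 is None else beta0.copy()
        for _ in range(max_iter):
            eta = np.clip(A @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu)
            if not np.all(np.isfinite(w)) or w.max() < 1e-12:
                return beta, False
            H = A.T @ (A * w[:, None]) + lam * np.eye(A.shape[1])
            g = A.T @ (y - mu) - lam * beta
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return beta, False
            beta = beta + step
            if np.abs(step).max() < tol:
                return beta, True
            if np.abs(beta).max() > 1e6:
                return beta, False
        return beta, False

    beta, converged = irls(0.0)
    if converged:
        return beta, False
    beta, _ = irls(1e-6)
    return beta, True


def _predict_proba(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = np.clip(beta[0] + X @ beta[1:], -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# LOOCV


def loocv_probabilities(X_log: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Held-out predicted probabilities from leave-one-out cross-validation."""
    X = np.asarray(X_log, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 4:
        raise BiomarkerError("need n >= 4 for LOOCV")
    probs = np.empty(n)
    beta_full, _ = fit_logistic(X, y)  # warm start for the n leave-one-out fits
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise BiomarkerError("a training fold lost a class")
        beta, _ = fit_logistic(X[mask], y[mask], beta0=beta_full)
        probs[i] = _predict_proba(beta, X[i : i + 1])[0]
    return probs


def loocv_auc(conc: pd.DataFrame, metabolite_subset: list[str], labels: pd.Series) -> float:
    """LOOCV AUC of a logistic model on the natural-log concentrations."""
    sub = conc[metabolite_subset].dropna()
    y = labels.reindex(sub.index).to_numpy().astype(int)
    if (sub <= 0).any().any():
        raise BiomarkerError("non-positive concentrations cannot be log-transformed")
    probs = loocv_probabilities(np.log(sub.to_numpy()), y)
    return auc(probs, y)


# ---------------------------------------------------------------------------
# stepwise panel growth


@dataclass
class BiomarkerModel:
    """Selected panel with coefficients, AUC trajectory, ROC and confusion metrics."""

    selected: list[str]
    coefficients: np.ndarray | None  # intercept + per-metabolite (log scale)
    trajectory: list[float]  # LOOCV AUC per step
    probabilities: pd.Series | None  # held-out per-sample probabilities
    roc: np.ndarray | None  # (k, 2) FPR/TPR points
    metrics: dict = field(default_factory=dict)
    ridge_flag: bool = False

    @property
    def final_auc(self) -> float:
        return self.trajectory[-1] if self.trajectory else 0.5

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "coefficients": None if self.coefficients is None else [float(b) for b in self.coefficients],
            "loocv_auc_trajectory": [float(a) for a in self.trajectory],
            "metrics": self.metrics,
            "ridge_flag": self.ridge_flag,
        }


def stepwise_select(
    candidates: CandidateSet,
    conc: pd.DataFrame,
    labels: pd.Series,
    config: PipelineConfig | None = None,
) -> BiomarkerModel:
    """Greedy forward search over candidates scored by LOOCV AUC.

    The best addition is accepted iff it strictly increases the AUC; ties are
    broken by lower q-value, then lexicographic id. An empty candidate set
    yields the null model (AUC 0.5).
    """
    config = config or PipelineConfig()
    pool = list(candidates.members)
    qv = candidates.flags["q_value"]
    selected: list[str] = []
    trajectory: list[float] = []
    best_auc = 0.0

    while pool:
        scored = []
        for mid in pool:
            try:
                a = loocv_auc(conc, selected + [mid], labels)
            except BiomarkerError:
                continue
            scored.append((-a, float(qv.get(mid, np.inf)), mid, a))
        if not scored:
            break
        scored.sort()
        _, _, best_mid, a = scored[0]
        if a <= best_auc:
            break
        selected.append(best_mid)
        trajectory.append(a)
        best_auc = a
        pool.remove(best_mid)

    if not selected:
        return BiomarkerModel([], None, [], None, None, {"note": "no candidates passed the screen"})

    sub = conc[selected].dropna()
    y = labels.reindex(sub.index)
    beta, ridge = fit_logistic(np.log(sub.to_numpy()), y.to_numpy().astype(int))
    probs = pd.Series(loocv_probabilities(np.log(sub.to_numpy()), y.to_numpy().astype(int)), index=sub.index)
    roc = roc_curve(probs.to_numpy(), y.to_numpy())
    metrics = classify(probs.to_numpy(), y.to_numpy(), config.prob_threshold)
    return BiomarkerModel(selected, beta, trajectory, probs, roc, metrics, ridge)


# ---------------------------------------------------------------------------
# ROC and threshold classification


def roc_curve(probabilities, labels) -> np.ndarray:
    """All-thresholds ROC staircase from (0,0) to (1,1); trapezoid area = AUC."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise BiomarkerError("both classes must be present")
    order = np.argsort(-p, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    # group tied scores so ties produce diagonal segments
    i = 0
    ps, ys = p[order], y[order]
    while i < len(ys):
        j = i
        while j < len(ys) and ps[j] == ps[i]:
            j += 1
        tp += int((ys[i:j] == 1).sum())
        fp += int((ys[i:j] == 0).sum())
        points.append((fp / n0, tp / n1))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return np.asarray(points)


def roc_auc(roc: np.ndarray) -> float:
    """Trapezoid area under an ROC point set."""
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def classify(probabilities, labels, threshold: float = 0.5) -> dict:
    """Confusion metrics with the strict rule: predicted positive iff p > threshold."""
    if not 0 < threshold < 1:
        raise BiomarkerError("threshold must lie in (0,1)")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (p > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def metrics_from_counts(correct_by_group: dict[str, tuple[int, int]]) -> float:
    """Pooled sensitivity from per-group (correctly predicted, group size) counts."""
    tp = sum(c for c, _ in correct_by_group.values())
    n = sum(t for _, t in correct_by_group.values())
    return tp / n
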