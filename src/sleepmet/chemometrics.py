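"""Chemometrics: scaling, PCA with Hotelling T², and OPLS-DA.

The OPLS-DA implementation follows the orthogonal-filtering formulation for a
single response: the predictive weight is w ∝ Xᵀy; each orthogonal component
removes X-variation orthogonal to w (w_o ∝ p − (wᵀp)w, t_o = X w_o, deflation
X ← X − t_o p_oᵀ); the final predictive component is extracted from the
deflated matrix. Model quality is summarized by R²X, R²Y and the
cross-validated Q²Y (1 − PRESS/SS), with CV-ANOVA and label-permutation tests
for significance. p(corr) is the Pearson correlation between the predictive
score and each (scaled) variable.

The class vector is coded 0/1 and centered before fitting; by convention
positive p(corr) means higher levels in the second (y = 1) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class ChemometricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScaledMatrix:
    """Column-scaled data matrix retaining the centering/scaling parameters."""

    X: np.ndarray
    means: np.ndarray
    divisors: np.ndarray
    method: str

    def apply(self, X_new: np.ndarray) -> np.ndarray:
        """Scale new rows with the stored parameters."""
        return (np.asarray(X_new, dtype=float) - self.means) / self.divisors


def scale_matrix(X, method: str = "uv") -> ScaledMatrix:
    """Center ('center'), unit-variance ('uv') or Pareto ('pareto') scale columns.

    Pareto divides each centered column by the square root of its standard
    deviation. Zero-variance columns are centered only (with a warning).
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ChemometricsError("empty matrix")
    if np.isnan(X).all(axis=0).any():
        raise ChemometricsError("all-missing column")
    if method not in ("center", "uv", "pareto"):
        raise ChemometricsError(f"unknown scaling method {method!r}")
    means = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s): centered only", stacklevel=2)
    if method == "center":
        div = np.ones_like(sd)
    elif method == "uv":
        div = np.where(zero, 1.0, sd)
    else:
        div = np.where(zero, 1.0, np.sqrt(sd))
    return ScaledMatrix((X - means) / div, means, div, method)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: np.ndarray  # n × A
    loadings: np.ndarray  # p × A, orthonormal columns
    explained_variance: np.ndarray  # per component
    r2x_cum: float
    n_samples: int

    def hotelling_t2(self) -> np.ndarray:
        """Per-sample Hotelling T² over the fitted components."""
        lam = self.scores.var(axis=0, ddof=1)
        return ((self.scores**2) / lam).sum(axis=1)

    def t2_limit(self, level: float = 0.99) -> float:
        """F-distribution T² limit: A(n−1)(n+1)/(n(n−A)) · F(level; A, n−A)."""
        n, a = self.n_samples, self.scores.shape[1]
        if n <= a:
            raise ChemometricsError("T² limit needs n > number of components")
        f = sps.f.ppf(level, a, n - a)
        return float(a * (n - 1) * (n + 1) / (n * (n - a)) * f)


def fit_pca(X_scaled: np.ndarray, n_comp: int) -> PcaModel:
    """PCA of a scaled (at least centered) matrix via singular decomposition."""
    X = np.asarray(X_scaled, dtype=float)
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    if n_comp > rank:
        raise ChemometricsError(f"n_comp={n_comp} exceeds matrix rank {rank}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_comp] * s[:n_comp]
    loadings = vt[:n_comp].T
    ev = s[:n_comp] ** 2 / (n - 1)
    total = (X**2).sum()
    r2x_cum = float((s[:n_comp] ** 2).sum() / total) if total > 0 else 1.0
    return PcaModel(scores, loadings, ev, r2x_cum, n)


def pca_outlier_flag(model: PcaModel, sample_ids, level: float = 0.99) -> list:
    """Sample ids whose Hotelling T² exceeds the F-limit at the given level."""
    t2 = model.hotelling_t2()
    if np.allclose(t2, t2[0]):
        return []
    lim = model.t2_limit(level)
    return [sid for sid, v in zip(sample_ids, t2) if v > lim]


# ---------------------------------------------------------------------------
# OPLS


@dataclass
class OplsModel:
    """Fitted OPLS(-DA) model with one predictive and n_orth orthogonal components."""

    w: np.ndarray  # predictive weight (unit norm)
    t: np.ndarray  # predictive score
    p: np.ndarray  # predictive X-loading
    c: float  # y-loading
    W_o: np.ndarray  # p × n_orth orthogonal weights
    T_o: np.ndarray  # n × n_orth orthogonal scores
    P_o: np.ndarray  # p × n_orth orthogonal loadings
    r2x: float
    r2y: float
    y_mean: float
    n_orth: int
    q2y: float | None = None
    pcorr: np.ndarray | None = None
    cv_anova_p: float | None = None
    permutation_p: float | None = None

    @property
    def n_components(self) -> str:
        """Component count in the '1 + n_orth' convention."""
        return f"1 + {self.n_orth}"

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        """Predicted (centered-scale) y for scaled rows."""
        X = np.asarray(X_scaled, dtype=float).copy()
        for k in range(self.n_orth):
            t_o = X @ self.W_o[:, k]
            X -= np.outer(t_o, self.P_o[:, k])
        return (X @ self.w) * self.c + self.y_mean


def _as_class_vector(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ChemometricsError("class vector is constant")
    if len(classes) > 2:
        raise ChemometricsError("OPLS-DA supports exactly two classes")
    return np.where(y == classes[1], 1.0, 0.0)


def fit_opls(X_scaled: np.ndarray, y, n_orth: int = 0) -> OplsModel:
    """Fit OPLS with one predictive and ``n_orth`` orthogonal components."""
    X = np.asarray(X_scaled, dtype=float).copy()
    y01 = _as_class_vector(y)
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ss_y = float(yc @ yc)
    ss_x = float((X**2).sum())

    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ChemometricsError("predictive weight is ~0: y orthogonal to all columns")
    w /= nw

    n, p = X.shape
    W_o = np.zeros((p, n_orth))
    T_o = np.zeros((n, n_orth))
    P_o = np.zeros((p, n_orth))
    Xd = X.copy()
    for k in range(n_orth):
        t = Xd @ w
        pv = Xd.T @ t / (t @ t)
        w_o = pv - (w @ pv) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-12:
            warnings.warn("no orthogonal variation left; fewer components fitted", stacklevel=2)
            W_o, T_o, P_o = W_o[:, :k], T_o[:, :k], P_o[:, :k]
            n_orth = k
            break
        w_o /= nwo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, k], T_o[:, k], P_o[:, k] = w_o, t_o, p_o

    t = Xd @ w
    pv = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    resid = yc - c * t
    r2y = 1.0 - float(resid @ resid) / ss_y if ss_y > 0 else 1.0
    modelled = float((t**2).sum() * (pv @ pv)) + float(
        sum((T_o[:, k] ** 2).sum() * (P_o[:, k] @ P_o[:, k]) for k in range(n_orth))
    )
    r2x = modelled / ss_x if ss_x > 0 else 1.0
    return OplsModel(w, t, pv, c, W_o, T_o, P_o, min(r2x, 1.0), r2y, y_mean, n_orth)


def pcorr_loadings(model: OplsModel, X_scaled: np.ndarray) -> np.ndarray:
    """p(corr): Pearson correlation of the predictive score with each column.

    Zero-variance columns get p(corr) = 0 with a warning.
    """
    X = np.asarray(X_scaled, dtype=float)
    t = model.t - model.t.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    st = np.sqrt((t**2).sum())
    zero = sx == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance column(s): p(corr) set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ t) / (sx * st)
    r[zero] = 0.0
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# cross-validation


def _fold_assignment(n: int, folds: int) -> np.ndarray:
    """Deterministic interleaved fold assignment by sample order."""
    return np.arange(n) % folds


def cross_val_predictions(X_scaled: np.ndarray, y, n_orth: int, folds: int = 7) -> np.ndarray:
    """Held-out predictions (on the centered 0/1 scale) from k-fold CV."""
    X = np.asarray(X_scaled, dtype=float)
    y01 = _as_class_vector(y)
    n = len(y01)
    if folds < 2:
        raise ChemometricsError("folds must be >= 2")
    folds = min(folds, n)
    assign = _fold_assignment(n, folds)
    pred = np.empty(n)
    for f in range(folds):
        test = assign == f
        ytr = y01[~test]
        if len(np.unique(ytr)) < 2:
            raise ChemometricsError(f"training set of fold {f} lost a class")
        m = fit_opls(X[~test], ytr, n_orth)
        pred[test] = m.predict(X[test])
    return pred


def q2_cross_validation(X_scaled: np.ndarray, y, n_orth: int, folds: int = 7) -> float:
    """Q² = 1 − PRESS/SS over deterministic interleaved folds."""
    y01 = _as_class_vector(y)
    pred = cross_val_predictions(X_scaled, y01, n_orth, folds)
    press = float(((y01 - pred) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / ss


def select_n_orthogonal(
    X_scaled: np.ndarray, y, max_orth: int = 5, folds: int = 7, min_gain: float = 0.01
) -> int:
    """Greedily add orthogonal components while Q² improves by more than min_gain."""
    best_q2 = q2_cross_validation(X_scaled, y, 0, folds)
    n_orth = 0
    for k in range(1, max_orth + 1):
        try:
            q2 = q2_cross_validation(X_scaled, y, k, folds)
        except ChemometricsError:
            break
        if q2 > best_q2 + min_gain:
            best_q2, n_orth = q2, k
        else:
            break
    return n_orth


def cv_anova(X_scaled: np.ndarray, y, n_orth: int, folds: int = 7) -> float:
    """CV-ANOVA p-value: F-test of cross-validated residuals vs total y variation.

    F = ((SS_y − PRESS)/d1) / (PRESS/d2) with d1 the number of fitted latent
    components (1 + n_orth) and d2 = n − 1 − d1 residual degrees of freedom.
    The exact degrees-of-freedom bookkeeping of commercial implementations is
    proprietary, so p-values are approximate by design and should only be
    compared against a significance level, never digit-for-digit.
    """
    y01 = _as_class_vector(y)
    pred = cross_val_predictions(X_scaled, y01, n_orth, folds)
    press = float(((y01 - pred) ** 2).sum())
    ss = float(((y01 - y01.mean()) ** 2).sum())
    d1 = 1 + n_orth
    d2 = len(y01) - 1 - d1
    if d2 <= 0:
        return 1.0
    f_stat = ((ss - press) / d1) / (press / d2)
    if not np.isfinite(f_stat) or f_stat <= 0:
        return 1.0
    return float(sps.f.sf(f_stat, d1, d2))


def permutation_test(
    X_scaled: np.ndarray,
    y,
    n_perm: int = 999,
    seed: int = 0,
    max_orth: int = 5,
    folds: int = 7,
) -> tuple[float, np.ndarray, float]:
    """Label-permutation validation of an OPLS-DA model.

    Each permutation refits the full procedure (including orthogonal-component
    selection); p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1). Returns
    (p, null Q² distribution, observed Q²).
    """
    if n_perm < 99:
        raise ChemometricsError("n_perm must be >= 99")
    y01 = _as_class_vector(y)
    rng = np.random.default_rng(seed)

    def _q2(labels: np.ndarray) -> float:
        n_orth = select_n_orthogonal(X_scaled, labels, max_orth, folds)
        return q2_cross_validation(X_scaled, labels, n_orth, folds)

    q2_obs = _q2(y01)
    null = np.empty(n_perm)
    for i in range(n_perm):
        while True:
            perm = rng.permutation(y01)
            if len(np.unique(perm)) == 2:
                break
        null[i] = _q2(perm)
    p = (1 + int((null >= q2_obs).sum())) / (n_perm + 1)
    return p, null, q2_obs


def fit_opls_da(
    X_scaled: np.ndarray,
    y,
    max_orth: int = 5,
    folds: int = 7,
    n_perm: int | None = None,
    seed: int = 0,
) -> OplsModel:
    """Full OPLS-DA workflow: component selection, fit, Q², p(corr), CV-ANOVA."""
    y01 = _as_class_vector(y)
    n_orth = select_n_orthogonal(X_scaled, y01, max_orth, folds)
    model = fit_opls(X_scaled, y01, n_orth)
    model.q2y = q2_cross_validation(X_scaled, y01, n_orth, folds)
    model.pcorr = pcorr_loadings(model, X_scaled)
    model.cv_anova_p = cv_anova(X_scaled, y01, n_orth, folds)
    if n_perm:
        model.permutation_p, _, _ = permutation_test(X_scaled, y01, n_perm, seed, max_orth, folds)
    return model
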