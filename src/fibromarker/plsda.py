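"""NIPALS PLS-DA with VIP scoring and cross-validated R2/Q2.

The class label (stricture vs non-stricture) is coded 0/1 and regressed on
autoscaled expression by univariate-response partial least squares (PLS1),
extracted component-wise by NIPALS deflation. Per-gene importance is the
Variable Importance in Projection,

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),

whose squares average to 1 across the p genes, so VIP > 1 marks genes that
contribute more than an average gene; the selection rule is strict (VIP
strictly above the threshold). R2 is the fitted fraction of label variance;
Q2 = 1 - PRESS/TSS uses out-of-fold predictions (leave-one-out by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import StratifiedKFold, LeaveOneOut

from .containers import ExpressionMatrix

__all__ = ["PLSDA", "SelectionResult", "fit_plsda", "vip_scores", "cross_validate", "select_genes"]


class PLSDA(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Two-class PLS-DA via NIPALS (deterministic; y is the starting score).

    Parameters
    ----------
    n_components : int
        Number of latent components (default 2 — sample sizes here are tiny).
    scale : bool
        Autoscale columns to unit variance (default True; the convention
        under which a VIP threshold of 1 is interpretable).

    Attributes
    ----------
    x_weights_ : (p, A) normalized weight vectors w_a
    x_scores_ : (n, A) orthogonal score vectors t_a
    x_loadings_ : (p, A) loadings p_a
    y_loadings_ : (A,) per-component regression coefficients q_a
    ss_y_ : (A,) explained label sum of squares per component
    r2_ : cumulative fraction of label variance explained
    vip_ : per-gene VIP scores
    genes_ : column labels of the fitted predictors
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have different sample counts")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("PLS-DA requires exactly two classes")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("each class needs at least 2 samples")

        sd = X.std(axis=0, ddof=1).to_numpy()
        zero_var = sd == 0
        if zero_var.any() and self.scale:
            warnings.warn(
                f"excluding {int(zero_var.sum())} zero-variance gene(s) from the PLS fit",
                stacklevel=2,
            )
        keep = ~zero_var if self.scale else np.ones(X.shape[1], bool)
        self.genes_ = X.columns[keep]
        Xk = X.loc[:, self.genes_].to_numpy(dtype=float)

        self.x_mean_ = Xk.mean(axis=0)
        self.x_std_ = Xk.std(axis=0, ddof=1) if self.scale else np.ones(Xk.shape[1])
        self.y_mean_ = y.mean()
        Xc = (Xk - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_
        tss = float(yc @ yc)

        n, p = Xc.shape
        A = min(self.n_components, p, n - 1)
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ss = np.zeros(A)
        Xa, ya = Xc.copy(), yc.copy()
        for a in range(A):
            w = Xa.T @ ya
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                A = a
                break
            w /= nw
            t = Xa @ w
            tt = float(t @ t)
            if tt < 1e-12:
                A = a
                break
            pl = Xa.T @ t / tt
            qa = float(ya @ t) / tt
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, qa
            ss[a] = qa**2 * tt
            Xa = Xa - np.outer(t, pl)
            ya = ya - qa * t
        self.n_components_ = A
        self.x_weights_ = W[:, :A]
        self.x_scores_ = T[:, :A]
        self.x_loadings_ = P[:, :A]
        self.y_loadings_ = q[:A]
        self.ss_y_ = ss[:A]
        self.tss_ = tss
        self.r2_per_component_ = self.ss_y_ / tss if tss > 0 else np.zeros(A)
        self.r2_ = float(self.r2_per_component_.sum())
        self.vip_ = vip_scores(self)
        return self

    # -- prediction ------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "x_weights_"):
            raise ValueError("model is not fitted")

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the latent scores."""
        self._check_fitted()
        Xc = (pd.DataFrame(X).loc[:, self.genes_].to_numpy(dtype=float) - self.x_mean_) / self.x_std_
        T = np.zeros((Xc.shape[0], self.n_components_))
        Xa = Xc
        for a in range(self.n_components_):
            T[:, a] = Xa @ self.x_weights_[:, a]
            Xa = Xa - np.outer(T[:, a], self.x_loadings_[:, a])
        return T

    def decision_function(self, X) -> np.ndarray:
        """Continuous label prediction y_hat."""
        return self.y_mean_ + self.transform(X) @ self.y_loadings_

    def predict(self, X) -> np.ndarray:
        yhat = self.decision_function(X)
        cut = self.classes_.mean()
        return np.where(yhat >= cut, self.classes_[1], self.classes_[0])


def vip_scores(model: PLSDA) -> np.ndarray:
    """Variable Importance in Projection; sum of VIP^2 equals gene count."""
    model._check_fitted()
    W, ss = model.x_weights_, model.ss_y_
    p = W.shape[0]
    total = ss.sum()
    if total <= 0:
        warnings.warn("label orthogonal to predictors: VIP defined as zero", stacklevel=2)
        return np.zeros(p)
    norm = np.linalg.norm(W, axis=0)
    norm[norm == 0] = 1.0
    contrib = (W / norm) ** 2 @ ss
    return np.sqrt(p * contrib / total)


def fit_plsda(m: ExpressionMatrix, labels, n_components: int = 2) -> PLSDA:
    """Fit PLS-DA on a log-scale genes x samples matrix and binary labels."""
    if m.scale != "log":
        raise ValueError("fit_plsda expects a log-scale matrix")
    return PLSDA(n_components=n_components).fit(m.to_samples_by_genes(), np.asarray(labels))


def cross_validate(X, y, n_components: int = 2, folds: int | None = None,
                   random_state: int = 0) -> pd.DataFrame:
    """Cumulative R2 (full fit) and Q2 (out-of-fold) per component count.

    ``folds=None`` gives leave-one-out; otherwise stratified k-fold. Returns
    a frame indexed by component count with columns r2 and q2, plus the
    recommended component count (argmax Q2) in ``.attrs['recommended']``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    if folds is not None and folds > X.shape[0]:
        raise ValueError("folds cannot exceed the number of samples")
    full = PLSDA(n_components=n_components).fit(X, y)
    A = full.n_components_
    r2_cum = np.cumsum(full.r2_per_component_)

    if folds is None:
        splitter = LeaveOneOut()
        split = splitter.split(X)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=random_state)
        split = splitter.split(X, y)

    press = np.zeros(A)
    tss = float(((y - y.mean()) ** 2).sum())
    for train, test in split:
        ytr = y[train]
        if np.unique(ytr).size < 2:
            raise ValueError("a fold lost one class; use stratified folds or fewer folds")
        sub = PLSDA(n_components=A).fit(X.iloc[train], ytr)
        Tte = sub.transform(X.iloc[test])
        for a in range(A):
            used = min(a + 1, sub.n_components_)
            yhat = sub.y_mean_ + Tte[:, :used] @ sub.y_loadings_[:used]
            press[a] += float(((y[test] - yhat) ** 2).sum())
    q2_cum = 1.0 - press / tss
    out = pd.DataFrame(
        {"r2": r2_cum, "q2": q2_cum}, index=pd.RangeIndex(1, A + 1, name="n_components")
    )
    out.attrs["recommended"] = int(out["q2"].idxmax()) if A else 0
    return out


@dataclass
class SelectionResult:
    """Genes whose VIP strictly exceeds the threshold, ranked by VIP."""

    genes: list
    vip: pd.Series
    threshold: float


def select_genes(model: PLSDA, threshold: float = 1.0) -> SelectionResult:
    """VIP > threshold selection, sorted by descending VIP."""
    model._check_fitted()
    vip = pd.Series(model.vip_, index=model.genes_, name="vip")
    sel = vip[vip > threshold].sort_values(ascending=False)
    return SelectionResult(genes=sel.index.tolist(), vip=sel, threshold=threshold)
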