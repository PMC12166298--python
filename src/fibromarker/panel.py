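"""Random-forest evaluation of gene panels: AUC with bootstrap CI.

A bagged tree ensemble (500 trees, sqrt(p) features per split, no depth
cap) scores each sample's probability of being a stricture from the panel's
expression columns. Out-of-sample scores come from stratified 5-fold
cross-validation pooled across folds (default), from out-of-bag votes, or
from resubstitution (optimistic; provided for comparison only). AUC is the
Mann-Whitney pair probability — the fraction of (positive, negative) pairs
in which the positive sample outscores the negative, ties counted 1/2 —
with a stratified percentile-bootstrap confidence interval on the pooled
score/label pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix

__all__ = ["PanelSpec", "AucResult", "auc_from_scores", "rf_panel_auc"]


@dataclass
class PanelSpec:
    """A named set of genes evaluated jointly as a classifier panel."""

    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene")


@dataclass
class AucResult:
    panel: str
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    scheme: str
    scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def auc_from_scores(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + P(equal)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _bootstrap_ci(scores, labels, n_boot, level, rng):
    """Percentile bootstrap of the AUC, resampling within each class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        s = np.concatenate([ps, ns])
        l = np.concatenate([np.ones(ps.size, bool), np.zeros(ns.size, bool)])
        aucs[b] = auc_from_scores(s, l)
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def rf_panel_auc(
    m: ExpressionMatrix,
    labels,
    panel: PanelSpec,
    n_trees: int = 500,
    scheme: str = "cv",
    seed: int | None = 0,
    cv_folds: int = 5,
    n_boot: int = 2000,
    ci_level: float = 0.95,
) -> AucResult:
    """Evaluate a panel's stricture-vs-non-stricture AUC with a bagged forest.

    ``scheme`` is ``"cv"`` (stratified k-fold, pooled out-of-fold
    probabilities; default), ``"oob"`` (out-of-bag votes) or ``"resub"``
    (in-sample, optimistic). The CI is a stratified percentile bootstrap of
    the pooled score/label pairs.
    """
    if m.scale != "log":
        raise ValueError("rf_panel_auc expects a log-scale matrix")
    labels = np.asarray(labels).astype(bool)
    X = m.subset_genes(panel.genes).to_samples_by_genes()
    if labels.size != X.shape[0]:
        raise ValueError("labels length must match the number of samples")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if min(n_pos, n_neg) < 3:
        raise ValueError("need at least 3 samples per class")

    rng = np.random.default_rng(seed)
    rf_seed = int(rng.integers(0, 2**31 - 1))
    Xa = X.to_numpy(dtype=float)
    y = labels.astype(int)

    def make_rf(oob=False):
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=rf_seed,
            oob_score=oob, bootstrap=True,
        )

    if scheme == "cv":
        folds = min(cv_folds, n_pos, n_neg)
        if folds < cv_folds:
            warnings.warn(f"reduced CV folds to {folds} so every fold sees both classes",
                          stacklevel=2)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rf_seed)
        scores = np.empty(y.size)
        for train, test in skf.split(Xa, y):
            rf = make_rf().fit(Xa[train], y[train])
            scores[test] = rf.predict_proba(Xa[test])[:, list(rf.classes_).index(1)]
    elif scheme == "oob":
        rf = make_rf(oob=True).fit(Xa, y)
        prob = rf.oob_decision_function_
        scores = np.nan_to_num(prob[:, list(rf.classes_).index(1)], nan=0.5)
    elif scheme == "resub":
        rf = make_rf().fit(Xa, y)
        scores = rf.predict_proba(Xa)[:, list(rf.classes_).index(1)]
    else:
        raise ValueError("scheme must be 'cv', 'oob' or 'resub'")

    auc = auc_from_scores(scores, labels)
    lo, hi = _bootstrap_ci(scores, labels, n_boot, ci_level, rng)
    lo, hi = min(lo, auc), max(hi, auc)
    return AucResult(
        panel=panel.name, auc=auc, ci_low=lo, ci_high=hi,
        n_pos=n_pos, n_neg=n_neg, scheme=scheme,
        scores=pd.Series(scores, index=X.index, name="score"),
    )
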