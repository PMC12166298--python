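"""Empirical-Bayes moderated-t differential expression.

Per gene, the two-group (or paired) sample variance s2_g on df_g residual
degrees of freedom is shrunk toward a pooled prior fitted across genes by
the method of moments on log variances, assuming a scaled inverse-chi-square
prior with hyperparameters (d0, s0^2):

    s2_tilde_g = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)
    t_g        = log2fc_g / sqrt(s2_tilde_g * c)

with c the contrast's variance coefficient (1/nA + 1/nB unpaired,
1/n_pairs paired on within-patient differences). P-values come from the t
distribution on d0 + df_g degrees of freedom; Benjamini-Hochberg adjustment
is applied across genes within a contrast. A gene is called differentially
expressed when adjusted P < alpha and |log2fc| >= log2(fold-change gate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, align_metadata

__all__ = [
    "EbPrior",
    "ContrastSpec",
    "OverlapResult",
    "fit_eb_prior",
    "bh_adjust",
    "ModeratedTTest",
    "moderated_t",
    "overlap_deg",
]


@dataclass
class EbPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior."""

    d0: float      # prior degrees of freedom; may be math.inf
    s0_sq: float   # prior variance

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


@dataclass
class ContrastSpec:
    """One pairwise site comparison, oriented group_a minus group_b."""

    name: str
    group_a: str
    group_b: str
    pairing: str = "paired"  # "paired" (by patient) or "unpaired"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")
        if self.pairing not in ("paired", "unpaired"):
            raise ValueError("pairing must be 'paired' or 'unpaired'")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_eb_prior(s2: np.ndarray, df_residual: float) -> EbPrior:
    """Fit (d0, s0^2) by moments of log sample variances.

    Under the scaled inverse-chi-square prior, log s2_g has known mean and
    variance offsets (digamma/trigamma of the half degrees of freedom);
    matching the observed mean and excess variance of log s2 yields the
    estimator. When the observed variance of log s2 does not exceed its
    expected sampling variance, d0 is flagged infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.ndim != 1 or s2.size < 10:
        raise ValueError("fit_eb_prior needs a 1-d vector of at least 10 variances")
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    if df_residual <= 0:
        raise ValueError("df_residual must be positive")
    # Degenerate branch: no dispersion at all -> point-mass prior at that value.
    if np.ptp(s2) == 0.0:
        return EbPrior(d0=math.inf, s0_sq=float(s2[0]))
    if np.any(s2 == 0):
        tiny = s2[s2 > 0].min() * 1e-8
        warnings.warn("zero variances floored before log-moment fit", stacklevel=2)
        s2 = np.maximum(s2, tiny)

    half = df_residual / 2.0
    e = np.log(s2) - special.digamma(half) + math.log(half)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, half))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return EbPrior(d0=d0, s0_sq=s0_sq)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def _t_sf2(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided P from t statistics; infinite df falls back to the normal."""
    t = np.asarray(t, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    p = np.empty_like(t)
    fin = np.isfinite(df)
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df[fin])
    p[~fin] = 2.0 * stats.norm.sf(np.abs(t[~fin]))
    return np.clip(p, np.nextafter(0, 1), 1.0)


class ModeratedTTest(BaseEstimator):
    """Moderated two-group t test over many genes (sklearn-style).

    ``fit(X, y)`` takes a samples x genes frame on the log2(TPM+1) scale and
    a binary/boolean group indicator ``y`` (True = group A). For the paired
    design, pass ``pairs`` (e.g. patient ids) aligned with rows; each pair
    must contribute exactly one sample per group.

    Parameters
    ----------
    alpha : float
        Adjusted-P significance gate (default 0.05).
    fc_threshold : float
        Fold-change gate on the natural scale; a gene must satisfy
        |log2fc| >= log2(fc_threshold) (default 2.0, i.e. |log2fc| >= 1).
    paired : bool
        Paired-by-patient (default) or unpaired pooled-variance design.
    prior : EbPrior or None
        Fixed prior; fitted from the data when None.

    Attributes
    ----------
    prior_, log2fc_, s2_, s2_tilde_, t_, df_total_, p_, p_adj_, is_deg_
    results_ : per-gene DataFrame of all of the above.
    """

    def __init__(self, alpha: float = 0.05, fc_threshold: float = 2.0,
                 paired: bool = True, prior: EbPrior | None = None):
        self.alpha = alpha
        self.fc_threshold = fc_threshold
        self.paired = paired
        self.prior = prior

    def fit(self, X: pd.DataFrame, y, pairs=None):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(bool)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y length must match the number of samples")
        genes = X.columns
        A, B = X.loc[y], X.loc[~y]

        if self.paired:
            if pairs is None:
                raise ValueError("paired design requires `pairs`")
            pairs = np.asarray(pairs)
            pa = pd.Series(pairs[y], name="pair")
            pb = pd.Series(pairs[~y], name="pair")
            common = pd.Index(pa).intersection(pd.Index(pb))
            if len(common) < 2:
                raise ValueError("paired design needs at least 2 complete pairs")
            a = A.set_index(pa).loc[common].to_numpy()
            b = B.set_index(pb).loc[common].to_numpy()
            diffs = a - b
            n_pairs = diffs.shape[0]
            lfc = diffs.mean(axis=0)
            s2 = diffs.var(axis=0, ddof=1)
            df_g = float(n_pairs - 1)
            c = 1.0 / n_pairs
        else:
            na, nb = A.shape[0], B.shape[0]
            if na < 2 or nb < 2:
                raise ValueError("each group needs at least 2 samples (unpaired)")
            lfc = A.mean(axis=0).to_numpy() - B.mean(axis=0).to_numpy()
            s2 = ((na - 1) * A.var(axis=0, ddof=1).to_numpy()
                  + (nb - 1) * B.var(axis=0, ddof=1).to_numpy()) / (na + nb - 2)
            df_g = float(na + nb - 2)
            c = 1.0 / na + 1.0 / nb

        lfc = np.asarray(lfc, dtype=float)
        s2 = np.asarray(s2, dtype=float)
        prior = self.prior if self.prior is not None else fit_eb_prior(s2, df_g)
        d0 = prior.d0
        if math.isinf(d0):
            s2_tilde = np.full_like(s2, prior.s0_sq)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_tilde = (d0 * prior.s0_sq + df_g * s2) / (d0 + df_g)
            df_total = np.full_like(s2, d0 + df_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / np.sqrt(s2_tilde * c)
        t = np.where(lfc == 0, 0.0, t)
        p = _t_sf2(t, df_total)
        p = np.where(t == 0, 1.0, p)
        p_adj = bh_adjust(p)
        is_deg = (p_adj < self.alpha) & (np.abs(lfc) >= np.log2(self.fc_threshold))

        self.prior_ = prior
        self.df_residual_ = df_g
        self.log2fc_, self.s2_, self.s2_tilde_ = lfc, s2, s2_tilde
        self.t_, self.df_total_, self.p_, self.p_adj_, self.is_deg_ = t, df_total, p, p_adj, is_deg
        self.results_ = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": lfc,
                "s2": s2,
                "s2_tilde": s2_tilde,
                "t_mod": t,
                "df_total": df_total,
                "p_raw": p,
                "p_adj": p_adj,
                "is_deg": is_deg,
            }
        ).set_index("gene")
        return self


def moderated_t(
    contrast: ContrastSpec,
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    prior: EbPrior | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Run one pairwise site contrast; returns the per-gene result table."""
    if m.scale != "log":
        raise ValueError("moderated_t expects a filtered log-scale matrix")
    meta = align_metadata(m, meta)
    for site in (contrast.group_a, contrast.group_b):
        if site not in set(meta["site"]):
            raise ValueError(f"site {site!r} absent from metadata")
    keep = meta["site"].isin([contrast.group_a, contrast.group_b]).to_numpy()
    X = m.to_samples_by_genes().loc[keep]
    sub = meta.loc[keep]
    y = (sub["site"] == contrast.group_a).to_numpy()
    est = ModeratedTTest(alpha=alpha, fc_threshold=fc_threshold,
                         paired=contrast.pairing == "paired", prior=prior)
    est.fit(X, y, pairs=sub["patient_id"].to_numpy())
    res = est.results_.copy()
    res.attrs["contrast"] = contrast.name
    res.attrs["prior"] = (est.prior_.d0, est.prior_.s0_sq)
    return res


@dataclass
class OverlapResult:
    """Sign-consistent DEG overlap between two contrasts."""

    genes: pd.DataFrame          # index gene, columns log2fc_a, log2fc_b, direction
    n_up: int
    n_down: int
    n_deg_a: int
    n_deg_b: int
    per_contrast: dict = field(default_factory=dict)

    @property
    def n_overlap(self) -> int:
        return self.n_up + self.n_down


def overlap_deg(a: pd.DataFrame, b: pd.DataFrame) -> OverlapResult:
    """Genes called DEG in both contrasts with the same fold-change sign."""
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("contrast results cover different gene universes")
        b = b.loc[a.index]
    both = a["is_deg"].to_numpy() & b["is_deg"].to_numpy()
    same_sign = np.sign(a["log2fc"].to_numpy()) == np.sign(b["log2fc"].to_numpy())
    sel = both & same_sign
    genes = pd.DataFrame(
        {
            "log2fc_a": a["log2fc"].to_numpy()[sel],
            "log2fc_b": b["log2fc"].to_numpy()[sel],
        },
        index=a.index[sel],
    )
    genes["direction"] = np.where(genes["log2fc_a"] > 0, "up", "down")
    n_up = int((genes["direction"] == "up").sum())
    n_down = int((genes["direction"] == "down").sum())
    return OverlapResult(
        genes=genes,
        n_up=n_up,
        n_down=n_down,
        n_deg_a=int(a["is_deg"].sum()),
        n_deg_b=int(b["is_deg"].sum()),
    )
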