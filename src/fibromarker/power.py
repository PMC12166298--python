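"""Simulation-based power and sample-size estimation.

Expression is modelled as multivariate log-normal: the log2(TPM+1) values
have per-gene means ``mu`` and covariance ``sigma`` estimated from data
(the covariance repaired to the nearest positive-semidefinite matrix by
eigenvalue clipping when sampling noise makes it indefinite). For a target
gene, two groups of size n are drawn from the model; the second group's
log-mean for the target — and, optionally, for every gene whose model
correlation with the target is at least ``corr_threshold`` in absolute
value — is shifted by Cohen's d times that gene's log-scale standard
deviation. A one-way fixed-effects ANOVA (two groups: F = t^2) on the
target's log values yields a P value per replicate; power at n is the
rejection fraction over replicates, reported with its Monte-Carlo standard
error, and the required sample size is the smallest grid n reaching the
target power (75% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "LogNormalModel",
    "EffectSpec",
    "PowerCurve",
    "nearest_psd",
    "fit_lognormal",
    "simulate_two_groups",
    "anova_pvalue",
    "anova_sweep",
    "power_curve",
    "required_n",
    "cohens_d",
]

DEFAULT_GRID = (5, 10, 15, 20, 50, 100)


@dataclass
class LogNormalModel:
    """Multivariate normal model of log2(TPM+1) expression."""

    genes: list
    mu: np.ndarray
    sigma: np.ndarray
    repair_applied: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma shape does not match mu")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in model") from None

    def correlations_with(self, gene: str) -> np.ndarray:
        i = self.index_of(gene)
        sd = np.sqrt(np.diag(self.sigma))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.sigma[i] / (sd * sd[i])
        return np.nan_to_num(r, nan=0.0)

    def submodel(self, genes) -> "LogNormalModel":
        idx = [self.index_of(g) for g in genes]
        return LogNormalModel(
            genes=list(genes), mu=self.mu[idx],
            sigma=self.sigma[np.ix_(idx, idx)], repair_applied=self.repair_applied,
        )


@dataclass
class EffectSpec:
    """Cohen's-d effect on a target gene, optionally propagated to its
    highly correlated neighbours (|r| >= corr_threshold, default 0.8)."""

    target: str
    d: float
    corr_threshold: float = 0.8
    propagate: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [0, 1]")


@dataclass
class PowerCurve:
    target: str
    d: float
    n_grid: tuple
    power: np.ndarray
    mc_se: np.ndarray
    n_reps: int
    alpha: float
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.n_grid)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("n_grid must be strictly increasing")
        if np.any((self.power < 0) | (self.power > 1)):
            raise ValueError("power values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_per_group": list(self.n_grid), "power": self.power, "mc_se": self.mc_se}
        )


def nearest_psd(sigma: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues at zero; flag whether clipping changed it."""
    sigma = np.asarray(sigma, dtype=float)
    sym = (sigma + sigma.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        repaired = w.min() < 0
        w = np.clip(w, 0.0, None)
        return (v * w) @ v.T if repaired else sym, False
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T, True


def fit_lognormal(m: ExpressionMatrix, genes=None) -> LogNormalModel:
    """Estimate mu and sigma of log2(TPM+1) for the given genes."""
    if m.scale == "tpm":
        X = np.log2(m.values.to_numpy(dtype=float) + 1.0)
    else:
        X = m.values.to_numpy(dtype=float)
    gene_ids = list(m.genes)
    if genes is not None:
        idx = [gene_ids.index(g) for g in genes]
        X = X[idx]
        gene_ids = list(genes)
    n = X.shape[1]
    if n < 3:
        raise ValueError("fit_lognormal needs at least 3 samples")
    if X.shape[0] > n:
        warnings.warn(
            "more genes than samples: the covariance estimate is singular by "
            "construction; consider a smaller gene subset", stacklevel=2,
        )
    mu = X.mean(axis=1)
    sigma = np.cov(X, ddof=1)
    sigma = np.atleast_2d(sigma)
    zero_var = np.diag(sigma) == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} constant gene(s) in the model", stacklevel=2)
    sigma, repaired = nearest_psd(sigma)
    return LogNormalModel(genes=gene_ids, mu=mu, sigma=sigma, repair_applied=repaired)


def _sampling_factor(sigma: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((sigma + sigma.T) / 2.0)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _shifted_mu(model: LogNormalModel, effect: EffectSpec) -> np.ndarray:
    sd = np.sqrt(np.diag(model.sigma))
    i = model.index_of(effect.target)
    mu_b = model.mu.copy()
    if effect.propagate:
        r = np.abs(model.correlations_with(effect.target))
        shifted = r >= effect.corr_threshold
        shifted[i] = True
    else:
        shifted = np.zeros(model.mu.size, bool)
        shifted[i] = True
    mu_b[shifted] += effect.d * sd[shifted]
    return mu_b


def simulate_two_groups(
    model: LogNormalModel, effect: EffectSpec, n_per_group: int, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw TPM-scale genes x samples tables for a null and a shifted group."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    L = _sampling_factor(model.sigma)
    g = model.mu.size
    za = rng.standard_normal((n_per_group, g))
    zb = rng.standard_normal((n_per_group, g))
    mu_b = _shifted_mu(model, effect)
    a = np.exp2(model.mu + za @ L.T).T
    b = np.exp2(mu_b + zb @ L.T).T
    cols_a = [f"A{j + 1:03d}" for j in range(n_per_group)]
    cols_b = [f"B{j + 1:03d}" for j in range(n_per_group)]
    return (
        pd.DataFrame(a, index=model.genes, columns=cols_a),
        pd.DataFrame(b, index=model.genes, columns=cols_b),
    )


def anova_pvalue(group_a, group_b) -> float:
    """One-way fixed-effects ANOVA P for two groups (F = t^2).

    Degenerate inputs: zero within-group variance with equal means gives
    p = 1 by convention (flagged); with unequal means, p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            warnings.warn("degenerate ANOVA: no variance, equal means; p = 1", stacklevel=2)
            return 1.0
        return 0.0
    f, p = stats.f_oneway(a, b)
    return float(p)


def anova_sweep(group_a: pd.DataFrame, group_b: pd.DataFrame) -> pd.Series:
    """Per-variable ANOVA screen over every gene of two TPM-scale tables."""
    la = np.log2(group_a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(group_b.to_numpy(dtype=float) + 1.0)
    p = _two_group_f_pvalues(la.T, lb.T)
    return pd.Series(p, index=group_a.index, name="p_anova")


def _two_group_f_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-group one-way ANOVA over columns of (n, k) arrays."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    grand = (na * ma + nb * mb) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((a - ma) ** 2).sum(axis=0) + ((b - mb) ** 2).sum(axis=0)
    df1, df2 = 1, na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(f, df1, df2)
    p = np.where(ss_within == 0, np.where(ss_between == 0, 1.0, 0.0), p)
    return np.asarray(p, dtype=float)


def power_curve(
    model: LogNormalModel,
    effect: EffectSpec,
    n_grid=DEFAULT_GRID,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> PowerCurve:
    """Monte-Carlo power of the target-gene ANOVA over a sample-size grid.

    Only the target gene's marginal is simulated: the readout is its
    per-replicate two-group ANOVA, and marginalising a multivariate normal
    is exact, so the other genes' draws cannot change the result.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    grid = tuple(int(n) for n in n_grid)
    i = model.index_of(effect.target)
    mu_t = model.mu[i]
    sd_t = float(np.sqrt(model.sigma[i, i]))
    children = np.random.SeedSequence(seed).spawn(len(grid))
    power = np.empty(len(grid))
    for k, n in enumerate(grid):
        rng = np.random.default_rng(children[k])
        a = rng.normal(mu_t, sd_t, size=(n, n_reps))
        b = rng.normal(mu_t + effect.d * sd_t, sd_t, size=(n, n_reps))
        p = _two_group_f_pvalues(a, b)
        power[k] = float((p < alpha).mean())
    mc_se = np.sqrt(power * (1.0 - power) / n_reps)
    return PowerCurve(
        target=effect.target, d=effect.d, n_grid=grid, power=power,
        mc_se=mc_se, n_reps=n_reps, alpha=alpha, seed=seed,
    )


def required_n(curve: PowerCurve, target_power: float = 0.75):
    """Smallest grid n with power >= target_power, or None if not reached."""
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    for n, pw in zip(curve.n_grid, curve.power):
        if pw >= target_power:
            return int(n)
    return None


def cohens_d(group_a, group_b) -> float:
    """Pooled-SD standardized mean difference between two value vectors."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))
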