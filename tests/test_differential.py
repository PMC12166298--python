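"""Moderated-t machinery: prior fit, shrinkage formula, BH, overlap."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fibromarker import (
    ContrastSpec,
    EbPrior,
    ExpressionMatrix,
    ModeratedTTest,
    bh_adjust,
    fit_eb_prior,
    moderated_t,
    overlap_deg,
)


def brute_force_bh(p):
    """Step-up from the definition: adj_(i) = min_{j>=i} m*p_(j)/j, by loops."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        adj[idx] = min(1.0, min(candidates))
    return adj


# ---------------------------------------------------------------- prior fit

def test_prior_zero_dispersion_returns_point_mass():
    prior = fit_eb_prior(np.full(50, 2.0), df_residual=4)
    assert math.isinf(prior.d0)
    assert prior.s0_sq == pytest.approx(2.0)


def test_prior_recovery_from_scaled_inv_chisq():
    rng = np.random.default_rng(2024)
    d0, s0, df, g = 4.0, 1.0, 4, 20000
    sigma2 = d0 * s0 / rng.chisquare(d0, g)
    s2 = sigma2 * rng.chisquare(df, g) / df
    prior = fit_eb_prior(s2, df_residual=df)
    assert prior.d0 == pytest.approx(d0, abs=0.5)
    assert prior.s0_sq == pytest.approx(s0, abs=0.1)


def test_prior_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_eb_prior(np.array([1.0, 2.0]), df_residual=4)


# ---------------------------------------------------------------- moderated t

def _two_group_frame(a_rows, b_rows):
    """Build samples x genes frame from per-group gene-major value lists."""
    X = np.vstack([np.asarray(a_rows, float).T, np.asarray(b_rows, float).T])
    y = np.array([True] * np.asarray(a_rows).shape[1] + [False] * np.asarray(b_rows).shape[1])
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])]), y


def test_shrinkage_formula_hand_example():
    """n=3 vs 3, mean diff 2, s2=1, prior (d0=4, s0=1): t = 2/sqrt(2/3)."""
    a = [[2, 3, 4]]   # mean 3, var 1
    b = [[0, 1, 2]]   # mean 1, var 1
    X, y = _two_group_frame(a, b)
    est = ModeratedTTest(paired=False, prior=EbPrior(4.0, 1.0)).fit(X, y)
    assert est.s2_tilde_[0] == pytest.approx(1.0)
    assert est.t_[0] == pytest.approx(2 / math.sqrt(2 / 3), abs=1e-9)
    assert est.df_total_[0] == pytest.approx(8.0)


def test_null_gene_gives_t_zero_p_one():
    X, y = _two_group_frame([[1, 2, 3]], [[3, 2, 1]])
    est = ModeratedTTest(paired=False, prior=EbPrior(4.0, 1.0)).fit(X, y)
    assert est.t_[0] == 0.0
    assert est.p_[0] == 1.0


def test_zero_prior_df_reproduces_ordinary_t(rng):
    X = pd.DataFrame(rng.normal(size=(12, 40)), columns=[f"g{i}" for i in range(40)])
    y = np.array([True] * 6 + [False] * 6)
    est = ModeratedTTest(paired=False, prior=EbPrior(0.0, 1.0)).fit(X, y)
    t_ref, p_ref = stats.ttest_ind(X[y], X[~y], equal_var=True)
    np.testing.assert_allclose(est.t_, t_ref, atol=1e-9)
    np.testing.assert_allclose(est.p_, p_ref, atol=1e-9)


def test_monotone_in_mean_difference():
    base_a, base_b = [0.0, 1.0, 2.0], [0.0, 1.0, 2.0]
    prev = -1.0
    for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
        X, y = _two_group_frame([[v + shift for v in base_a]], [base_b])
        est = ModeratedTTest(paired=False, prior=EbPrior(4.0, 1.0)).fit(X, y)
        assert abs(est.t_[0]) >= prev
        prev = abs(est.t_[0])


def test_moderated_p_uniform_under_null():
    """Heteroskedastic null matrix: moderated P values are uniform (KS)."""
    rng = np.random.default_rng(77)
    g = 5000
    sd = np.sqrt(4.0 / rng.chisquare(4.0, g))
    X = pd.DataFrame(rng.normal(0, 1, size=(10, g)) * sd, columns=[f"g{i}" for i in range(g)])
    y = np.array([True] * 5 + [False] * 5)
    est = ModeratedTTest(paired=False).fit(X, y)
    assert stats.kstest(est.p_, "uniform").pvalue > 0.01


def test_matches_limma_on_small_matrix(tmp_path):
    """Independent oracle: Bioconductor limma's lmFit/eBayes on a fixture."""
    rng = np.random.default_rng(42)
    g, n = 300, 6
    sd = np.sqrt(4.0 / rng.chisquare(4, g))
    X = rng.normal(0, 1, (g, n)) * sd[:, None]
    X[:30, 3:] += 1.5
    frame = pd.DataFrame(X, index=[f"g{i}" for i in range(g)],
                         columns=[f"s{j}" for j in range(n)])
    frame.to_csv(tmp_path / "expr.tsv", sep="\t")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("expr.tsv", row.names=1))
        design <- model.matrix(~factor(c(0,0,0,1,1,1)))
        fit <- eBayes(lmFit(x, design))
        write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                             d0=fit$df.prior, s0=fit$s2.prior), "limma_out.csv")
    """)
    (tmp_path / "limma.R").write_text(script)
    subprocess.run(["Rscript", "limma.R"], cwd=tmp_path, check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
    est = ModeratedTTest(paired=False).fit(frame.T, np.array([0, 0, 0, 1, 1, 1], bool))
    assert est.prior_.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert est.prior_.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
    np.testing.assert_allclose(est.t_, ref["t"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(est.p_, ref["p"].to_numpy(), atol=1e-8)


def test_paired_contrast_requires_pairs_and_enough_pairs():
    X = pd.DataFrame(np.arange(8.0).reshape(4, 2), columns=["g0", "g1"])
    y = np.array([True, True, False, False])
    with pytest.raises(ValueError, match="pairs"):
        ModeratedTTest(paired=True).fit(X, y)
    with pytest.raises(ValueError, match="pairs"):
        ModeratedTTest(paired=True).fit(X, y, pairs=["p1", "p2", "p3", "p4"])


# ---------------------------------------------------------------- BH

def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust(np.array([0.005, 0.011, 0.02, 0.04])),
        [0.02, 0.022, 0.02 * 4 / 3, 0.04],
    )


def test_bh_degenerate_vectors():
    assert bh_adjust(np.array([1.0, 1.0, 1.0])).tolist() == [1.0, 1.0, 1.0]
    assert bh_adjust(np.array([0.37])).tolist() == [0.37]
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.0, 0.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=12))
def test_bh_matches_brute_force(p):
    p = np.asarray(p)
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)
    assert (bh_adjust(p) >= p - 1e-15).all()


# ---------------------------------------------------------------- overlap

def _result_frame(entries):
    """entries: gene -> (log2fc, is_deg)"""
    return pd.DataFrame(
        {"log2fc": [v[0] for v in entries.values()], "is_deg": [v[1] for v in entries.values()]},
        index=list(entries.keys()),
    )


def test_overlap_set_logic_and_sign_partition():
    a = _result_frame({"g1": (2, True), "g2": (1, True), "g3": (-1, True), "g4": (3, False)})
    b = _result_frame({"g1": (-2, True), "g2": (2, True), "g3": (-2, True), "g4": (1, True)})
    ov = overlap_deg(a, b)
    # g1 flips sign, g4 not significant in a -> overlap is {g2 up, g3 down}
    assert sorted(ov.genes.index) == ["g2", "g3"]
    assert ov.n_up == 1 and ov.n_down == 1
    assert ov.n_overlap == 2


def test_overlap_rejects_mismatched_universe():
    a = _result_frame({"g1": (1, True)})
    b = _result_frame({"g2": (1, True)})
    with pytest.raises(ValueError, match="universe"):
        overlap_deg(a, b)


def test_moderated_t_site_contrast_orientation(default_cohort):
    """Contrast is stricture minus margin: injected up genes have log2fc > 0."""
    from fibromarker import filter_genes, log_transform

    _, matrix, meta, truth = default_cohort
    filt, _ = filter_genes(log_transform(matrix))
    res = moderated_t(ContrastSpec("sp", "stricture", "proximal"), filt, meta)
    up = [g for g in truth.loc[truth["direction"] == "up", "gene"] if g in res.index]
    assert (res.loc[up, "log2fc"] > 0).mean() > 0.95
    assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
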