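"""TMM normalization, the precision-weighted moderated test and the
decreased/increased/control classification rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromshift.difftest import (classify_features, moderated_test,
                                 tmm_factors)
from chromshift.simulate import simulate_null_counts
from chromshift.stats import bh_adjust

GROUPS = np.array(["ctrl"] * 3 + ["trt"] * 3)


def test_tmm_identical_columns_unit_factors():
    col = np.array([10.0, 200, 35, 80, 5, 400])
    counts = np.tile(col[:, None], (1, 4))
    np.testing.assert_allclose(tmm_factors(counts), np.ones(4))


def test_tmm_doubled_column_closed_form():
    col = np.array([10.0, 200, 35, 80, 5, 400, 77, 31, 250, 18])
    counts = np.stack([col, 2 * col], axis=1)
    np.testing.assert_allclose(
        tmm_factors(counts), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-6)


def test_tmm_geometric_mean_one_on_random_counts():
    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(10, 0.05, size=(500, 6)).astype(float)
    f = tmm_factors(counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def test_tmm_rejects_all_zero_sample():
    counts = np.ones((10, 3))
    counts[:, 1] = 0
    with pytest.raises(ValueError):
        tmm_factors(counts)


def test_single_replicate_group_rejected():
    counts = np.abs(np.random.default_rng(0).poisson(50, size=(20, 3)))
    with pytest.raises(ValueError):
        moderated_test(counts, np.ones(3), np.array(["a", "a", "b"]), "a", "b")


def test_zero_prior_reduces_to_weighted_t():
    """With the empirical-Bayes prior forced off, the statistic must equal
    the ordinary weighted two-group t-test computed from the same
    observation weights."""
    rng = np.random.default_rng(5)
    counts = rng.negative_binomial(5, 0.02, size=(300, 6)).astype(float)
    table, det = moderated_test(counts, np.ones(6), GROUPS, "ctrl", "trt",
                                prior_df=0, return_details=True)
    y, w, trt = det["y"], det["weights"], det["is_treated"]
    mu_c = (w[:, ~trt] * y[:, ~trt]).sum(1) / w[:, ~trt].sum(1)
    mu_t = (w[:, trt] * y[:, trt]).sum(1) / w[:, trt].sum(1)
    mu = np.where(trt[None, :], mu_t[:, None], mu_c[:, None])
    s2 = (w * (y - mu) ** 2).sum(1) / 4
    t_ref = (mu_t - mu_c) / np.sqrt(
        s2 * (1 / w[:, ~trt].sum(1) + 1 / w[:, trt].sum(1)))
    np.testing.assert_allclose(table["t"], t_ref, rtol=1e-10)
    p_ref = 2 * stats.t.sf(np.abs(t_ref), 4)
    np.testing.assert_allclose(table["p"], p_ref, rtol=1e-10)


def test_constant_counts_yield_finite_statistic():
    counts = np.full((50, 6), 100.0)
    counts[:25] = np.random.default_rng(1).poisson(100, size=(25, 6))
    table = moderated_test(counts, np.ones(6), GROUPS, "ctrl", "trt")
    const = table.iloc[25:]
    assert np.isfinite(const["t"]).all()


def test_group_label_swap_negates_log2fc():
    rng = np.random.default_rng(9)
    counts = rng.negative_binomial(8, 0.05, size=(200, 6)).astype(float)
    f = tmm_factors(counts)
    fwd = classify_features(moderated_test(counts, f, GROUPS, "ctrl", "trt"))
    rev = classify_features(moderated_test(counts, f, GROUPS, "trt", "ctrl"))
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-12)
    swap = {"decreased": "increased", "increased": "decreased",
            "control": "control", "unclassified": "unclassified"}
    assert (fwd["class"].map(swap) == rev["class"]).all()


def test_classification_rules():
    table = pd.DataFrame(
        {
            "feature": list("abc"),
            "log2fc": [-1.5, np.log2(1.02), 0.8],
            "p": [0.001, 0.6, 0.01],
            "q": [0.01, 0.9, 0.04],
        }
    )
    out = classify_features(table)
    assert out["class"].tolist() == ["decreased", "control", "unclassified"]


def test_bh_matches_stepup_brute_force():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    n = len(p)
    order = np.argsort(p)
    brute = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        brute[i] = prev
    np.testing.assert_allclose(q, brute)
    # permutation invariance
    perm = rng.permutation(n)
    np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])


def test_null_calibration_small():
    """Type-I error close to nominal on a modest null NB matrix (the
    full-size calibration runs in the acceptance suite)."""
    counts = simulate_null_counts(1500, n_rep=3, dispersion=0.1, seed=21)
    table = moderated_test(counts, tmm_factors(counts), GROUPS, "ctrl", "trt")
    frac = float((table["p"] < 0.05).mean())
    assert 0.03 < frac < 0.07


def test_against_edger_limma_oracle(tmp_path):
    """Independent cross-check of the whole engine against edgeR TMM and
    limma-voom on a small matrix."""
    import subprocess

    rng = np.random.default_rng(42)
    mu = np.exp(rng.normal(np.log(120), 0.8, size=250))
    counts = rng.negative_binomial(
        10, (10 / (10 + mu))[:, None] * np.ones((1, 6))).astype(float)
    counts[:20, 3:] = rng.negative_binomial(
        10, 10 / (10 + 4 * mu[:20, None] * np.ones((1, 3))))
    path = tmp_path / "counts.tsv"
    pd.DataFrame(counts, columns=list("abcdef")).to_csv(path, sep="\t",
                                                        index=False)
    rscript = f"""
    suppressMessages({{library(edgeR); library(limma)}})
    x <- as.matrix(read.delim('{path}'))
    grp <- factor(c('c','c','c','t','t','t'), levels=c('c','t'))
    d <- DGEList(x); d <- calcNormFactors(d, method='TMM')
    v <- voom(d, model.matrix(~grp))
    fit <- eBayes(lmFit(v, model.matrix(~grp)))
    tt <- topTable(fit, coef=2, number=Inf, sort.by='none')
    out <- data.frame(nf=rep(d$samples$norm.factors, length.out=nrow(tt)),
                      lib=rep(d$samples$lib.size, length.out=nrow(tt)),
                      lfc=tt$logFC, t=tt$t, p=tt$P.Value)
    write.table(out, '{tmp_path / "ref.tsv"}', sep='\t', row.names=FALSE)
    """
    rfile = tmp_path / "oracle.R"
    rfile.write_text(rscript)
    subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
    # combined factors = edgeR factor x library size, geometric mean 1
    edger = (ref["nf"] * ref["lib"]).to_numpy()[:6]
    edger = edger / np.exp(np.mean(np.log(edger)))
    mine = tmm_factors(counts)
    # reference-sample choice and trim-rank details differ slightly from
    # edgeR's implementation; factors agree to a few percent
    np.testing.assert_allclose(mine, edger, rtol=0.03)
    table = moderated_test(counts, mine,
                           GROUPS, "ctrl", "trt")
    np.testing.assert_allclose(table["log2fc"], ref["lfc"], atol=0.05)
    rho = stats.spearmanr(table["t"], ref["t"]).statistic
    assert rho > 0.99
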