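"""TF co-regulator discovery: target enrichment, MS detection, own-change
lookups, DAR motif odds ratios, partner classes and essentiality."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from chromshift.coregulators import (classify_partners, dar_motif_or,
                                     de_gene_sets, essentiality_enrichment,
                                     ms_filter, own_change,
                                     target_enrichment)
from chromshift.intervals import GenomicInterval
from chromshift.stats import hypergeom_upper_tail


def _universe(n):
    return {f"g{i}" for i in range(n)}


def test_hypergeometric_tail_matches_enumeration():
    # k=4 of K=10 targets, n=50 DE genes, N=1000
    N, K, n, k = 1000, 10, 50, 4
    brute = sum(
        comb(n, x, exact=True) * comb(N - n, K - x, exact=True)
        for x in range(k, min(K, n) + 1)
    ) / comb(N, K, exact=True)
    assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(brute, rel=1e-10)


def test_target_enrichment_extremes():
    universe = _universe(1000)
    de = {f"g{i}" for i in range(50)}
    enr = target_enrichment(
        {"tfA": de.copy(), "tfB": {f"g{i}" for i in range(900, 950)}},
        {"rna_up": de}, universe)
    pa = enr.loc[enr["tf"] == "tfA", "p_rna_up"].iloc[0]
    pb = enr.loc[enr["tf"] == "tfB", "p_rna_up"].iloc[0]
    assert pa < 1e-50 and pb > 0.9


def test_target_enrichment_requires_universe_containment():
    with pytest.raises(ValueError):
        target_enrichment({"tf": {"outsider"}}, {"up": set()}, _universe(10))


def test_ms_filter_and_alias_mapping():
    protein = pd.DataFrame({"feature": ["TF1", "P2"]})
    flags = ms_filter(["TF1", "TF2", "TF3"], protein,
                      id_map={"TF2": "P2", "TF3": "missing"})
    assert flags.tolist() == [True, True, False]


def test_own_change_missing_and_min_phospho():
    rna = pd.DataFrame({"feature": ["TF1"], "q": [0.01], "log2fc": [-1.0]})
    protein = pd.DataFrame({"feature": [], "q": [], "log2fc": []})
    phospho = pd.DataFrame({"feature": ["TF1_p1", "TF1_p2"],
                            "gene": ["TF1", "TF1"],
                            "q": [0.3, 0.01], "log2fc": [0.1, -0.9]})
    out = own_change(["TF1"], rna, protein, phospho)
    row = out.iloc[0]
    assert row["rna_fdr"] == 0.01
    assert np.isnan(row["protein_fdr"])  # absent -> missing, not 1.0
    assert row["phospho_fdr"] == 0.01    # min across peptides


def test_dar_motif_or_published_value_and_haldane():
    """From the printed tandem-site counts, log2 OR = log2(7.39)."""
    a, n1, c, n2 = 1244, 8042, 204, 8440
    lo = np.log2((a * (n2 - c)) / ((n1 - a) * c))
    assert lo == pytest.approx(np.log2(7.39), abs=0.01)
    # zero-cell input goes through the Haldane correction
    regions = [GenomicInterval("chr1", 0, 100)]
    control = [GenomicInterval("chr2", 0, 100)]
    hits = pd.DataFrame({"chrom": ["chr2"], "start": [10], "end": [20],
                         "strand": ["+"], "center": [15], "score": [5.0],
                         "p": [1e-5]})
    out = dar_motif_or(hits, regions, regions, control)
    assert np.isfinite(out["log2_or_decreased"])
    assert out["log2_or_decreased"] < 0 and out["haldane_decreased"]


def _report(enr, own, ms=True):
    return pd.DataFrame(
        {"tf": ["x"], "fdr_rna_up": [enr], "fdr_rna_down": [1.0],
         "fdr_protein_up": [1.0], "fdr_protein_down": [1.0],
         "rna_fdr": [own], "protein_fdr": [np.nan], "phospho_fdr": [np.nan],
         "ms_detected": [ms]}
    )


def test_partner_classification_rules():
    assert classify_partners(_report(1e-6, 0.001))["class"].iloc[0] == "evident"
    assert classify_partners(_report(1e-6, 0.5))["class"].iloc[0] == "hidden"
    assert classify_partners(_report(0.5, 0.001))["class"].iloc[0] == "none"
    assert classify_partners(_report(1e-6, 0.001, ms=False))["class"].iloc[0] == "none"


def test_partner_classification_monotone_in_threshold():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(30):
        rows.append(_report(rng.uniform(0, 0.2), rng.uniform(0, 0.2)))
    rep = pd.concat(rows, ignore_index=True)
    loose = (classify_partners(rep, enr_fdr=0.1)["class"] != "none").sum()
    tight = (classify_partners(rep, enr_fdr=0.01)["class"] != "none").sum()
    assert tight <= loose


def test_essentiality_enrichment_matches_enumeration():
    universe = {f"t{i}" for i in range(1639)}
    partners = set(list(universe)[:40])
    essential = set(list(universe)[32:149])  # 8 of 40 partners essential
    out = essentiality_enrichment(partners, essential, universe)
    assert (out["a"], out["b"], out["c"], out["d"]) == (8, 32, 109, 1490)
    # brute-force two-sided hypergeometric with point-probability rule
    from chromshift.stats import fisher_exact_two_sided

    assert out["p"] == pytest.approx(
        float(fisher_exact_two_sided(8, 32, 109, 1490)[0]))
    from scipy.stats import fisher_exact

    assert out["p"] == pytest.approx(
        fisher_exact([[8, 32], [109, 1490]]).pvalue, rel=1e-9)


def test_planted_partner_recovery(study):
    """On the default simulation all planted partners are found, evident/
    hidden kinds are assigned correctly, and no false partner appears."""
    universe = set(study.rna["feature"].astype(str))
    rna_up, rna_down = de_gene_sets(study.rna)
    prot_up, prot_down = de_gene_sets(study.protein)
    enr = target_enrichment(
        study.tf_targets,
        {"rna_up": rna_up, "rna_down": rna_down,
         "protein_up": prot_up, "protein_down": prot_down},
        universe)
    tfs = list(study.tf_targets)
    rep = enr.merge(own_change(tfs, study.rna, study.protein, study.phospho),
                    on="tf")
    rep["ms_detected"] = rep["tf"].map(ms_filter(tfs, study.protein))
    rep = classify_partners(rep)
    found = dict(zip(rep["tf"], rep["class"]))
    truth = dict(zip(study.truth.partners["tf"], study.truth.partners["kind"]))
    recovered = sum(found.get(tf, "none") != "none" for tf in truth)
    false = sum(cls != "none" and tf not in truth
                for tf, cls in found.items())
    assert recovered / len(truth) >= 0.9
    assert false <= 1
    for tf, kind in truth.items():
        assert found[tf] == kind
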