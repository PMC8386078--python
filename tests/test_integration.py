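"""Promoter assignment, DAR-DEG association, GSEA, insulator discovery,
loop grouping and TAD distances."""

import numpy as np
import pandas as pd
import pytest

from chromshift.integration import (GeneModel, InsulatorCandidate,
                                    assign_promoters, dar_deg_association,
                                    discover_insulators, gsea, gsea_es,
                                    loop_contact_change, make_topk_sets,
                                    tad_distance)
from chromshift.intervals import GenomicInterval
from chromshift.io import LoopRecord


def test_promoter_overlap_one_bp():
    genes = [GeneModel("g1", "chr1", 5000)]
    hits = assign_promoters([GenomicInterval("chr1", 4980, 5020)], genes)
    assert hits["gene"].tolist() == ["g1"]
    # promoter window is [tss-2000, tss+2000]; a region ending at its
    # left edge does not overlap, one extra bp does
    assert len(assign_promoters([GenomicInterval("chr1", 2000, 3000)],
                                genes)) == 0
    assert len(assign_promoters([GenomicInterval("chr1", 2000, 3001)],
                                genes)) == 1


def test_gene_with_two_tss_pairs_twice():
    genes = [GeneModel("g1", "chr1", 1000), GeneModel("g1", "chr1", 9000)]
    regions = [GenomicInterval("chr1", 900, 1100),
               GenomicInterval("chr1", 8900, 9100)]
    hits = assign_promoters(regions, genes)
    assert hits["gene"].tolist() == ["g1", "g1"]


def test_dar_deg_association_counts_and_haldane():
    pairs = pd.DataFrame({"region_index": [0, 1, 2, 3],
                          "gene": ["a", "b", "c", "d"]})
    region_classes = pd.Series(["decreased", "decreased", "control",
                                "control"])
    gene_classes = pd.Series({"a": "down", "b": "down", "c": "none",
                              "d": "none"})
    out = dar_deg_association(pairs, region_classes, gene_classes)
    dec = out.loc[out["dar_class"] == "decreased"].iloc[0]
    assert (dec["a"], dec["b"], dec["c"], dec["d"]) == (2, 0, 0, 2)
    assert dec["haldane"] and np.isfinite(dec["odds_ratio"])


def test_gsea_es_matches_hand_computed_running_sum():
    """5-gene toy ranking, equal weights (weight=0)."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    scores = np.array([2.0, 1.0, 0.5, -1.0, -2.0])
    gene_set = {"g1", "g3"}
    # hand computation: hit steps 1/2 at ranks 1 and 3, miss steps 1/3
    # running sum: 0.5, 0.5-1/3, 0.5-1/3+0.5, ..., extreme = +2/3
    es = gsea_es(genes, scores, gene_set, weight=0.0)
    assert es == pytest.approx(2 / 3)


def test_gsea_weighted_es_oracle():
    genes = ["g1", "g2", "g3", "g4", "g5"]
    scores = np.array([2.0, 1.0, 0.5, -1.0, -2.0])
    gene_set = {"g1", "g3"}
    # weight=1: hit increments |score|/sum(|scores in set|) = 2/2.5, 0.5/2.5
    dev = [2 / 2.5, 2 / 2.5 - 1 / 3, 2 / 2.5 - 1 / 3 + 0.5 / 2.5]
    assert gsea_es(genes, scores, gene_set, weight=1.0) == pytest.approx(
        max(dev))


def test_gsea_es_bounds_and_complement_negation():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(40)]
    scores = np.sort(rng.normal(size=40))[::-1]
    sets = {"s": set(genes[:10])}
    es = gsea_es(genes, scores, sets["s"], weight=0.0)
    comp = gsea_es(genes, scores, set(genes[10:]), weight=0.0)
    assert -1 <= es <= 1
    # equal-weights ES of the complement is the negation (up to the
    # discrete step where both deviations peak)
    assert es == pytest.approx(-comp, abs=1e-9)


def test_gsea_top_set_positive_and_null_uniformish():
    rng = np.random.default_rng(1)
    scores = pd.Series(np.sort(rng.normal(size=100))[::-1],
                       index=[f"g{i}" for i in range(100)])
    out = gsea(scores, {"top": set(scores.index[:10])}, n_perm=200, seed=0)
    assert out["es"].iloc[0] > 0 and out["p"].iloc[0] < 0.05


def test_gsea_skips_disjoint_set():
    scores = pd.Series([1.0, -1.0], index=["a", "b"])
    out = gsea(scores, {"x": {"zzz"}}, n_perm=10, seed=0)
    assert len(out) == 0


def test_topk_sets_nested_and_capped():
    table = pd.DataFrame({
        "feature": [f"g{i}" for i in range(30)],
        "log2fc": np.linspace(3, -3, 30),
        "q": [0.01] * 20 + [0.5] * 10,
    })
    sets = make_topk_sets(table, ks=(5, 10, 100))
    assert sets["top5"] <= sets["top10"] <= sets["top100"]
    assert len(sets["top100"]) == 20  # only significant genes available
    single = make_topk_sets(table, ks=(1,))
    assert len(single["top1"]) == 1


def _insulator_setup():
    regions = [GenomicInterval("chr1", 10_000, 10_500, name="r0"),
               GenomicInterval("chr1", 200_000, 200_500, name="r1")]
    summits = np.array([10_250, 200_250])
    table = pd.DataFrame({"feature": ["r0", "r1"],
                          "log2fc": [2.0, 2.0], "p": [1e-6, 1e-6],
                          "q": [1e-5, 1e-5],
                          "class": ["increased", "increased"]})
    ctcf = [GenomicInterval("chr1", 10_100, 10_400, name="c0")]
    conserved = np.array([True])
    genes = [GeneModel("gA", "chr1", 17_000),   # 6.75 kb away
             GeneModel("gB", "chr1", 262_000)]  # 61.75 kb from r1
    gene_table = pd.DataFrame({"feature": ["gA", "gB"],
                               "log2fc": [2.0, 2.0], "p": [1e-6, 1e-6],
                               "q": [1e-5, 1e-5]})
    loops = [LoopRecord(GenomicInterval("chr1", 10_000, 10_500),
                        GenomicInterval("chr1", 16_000, 18_000), "L0")]
    return regions, summits, table, ctcf, conserved, genes, gene_table, loops


def test_insulator_discovery_rules():
    (regions, summits, table, ctcf, conserved, genes, gene_table,
     loops) = _insulator_setup()
    out, counts = discover_insulators(table, regions, summits, ctcf,
                                      conserved, genes, gene_table, loops)
    # gA paired with r0 (6.75 kb, loop-supported); gB excluded: r1 has no
    # conserved CTCF peak and is 61.75 kb away anyway
    assert out["gene"].tolist() == ["gA"]
    assert bool(out["loop_support"].iloc[0])
    assert counts["step1_ctcf_overlap"] == 1


def test_insulator_excludes_gene_outside_window():
    (regions, summits, table, ctcf, conserved, genes, gene_table,
     loops) = _insulator_setup()
    far_genes = [GeneModel("gA", "chr1", 70_000)]  # ~60 kb away
    out, _ = discover_insulators(table, regions, summits, ctcf, conserved,
                                 far_genes, gene_table, loops)
    assert len(out) == 0


def test_insulator_requires_conserved_flag_column():
    (regions, summits, table, ctcf, conserved, genes, gene_table,
     loops) = _insulator_setup()
    with pytest.raises(ValueError):
        discover_insulators(table, regions, summits, ctcf, None, genes,
                            gene_table, loops)


def test_insulator_order_invariance():
    (regions, summits, table, ctcf, conserved, genes, gene_table,
     loops) = _insulator_setup()
    a, _ = discover_insulators(table, regions, summits, ctcf, conserved,
                               genes, gene_table, loops)
    b, _ = discover_insulators(table, regions, summits, ctcf, conserved,
                               list(reversed(genes)), gene_table, loops)
    pd.testing.assert_frame_equal(a, b)


def test_candidate_invariants():
    with pytest.raises(ValueError):
        InsulatorCandidate(GenomicInterval("chr1", 0, 100), "c", "g", 1000,
                           False)


def test_loop_contact_change_zero_and_grouping():
    regions = [GenomicInterval("chr1", 0, 100),
               GenomicInterval("chr1", 1000, 1100)]
    classes = np.array(["decreased", "unclassified"])
    loops = [LoopRecord(GenomicInterval("chr1", 0, 100),
                        GenomicInterval("chr1", 50_000, 50_100), "a"),
             LoopRecord(GenomicInterval("chr1", 1000, 1100),
                        GenomicInterval("chr1", 60_000, 60_100), "b")]
    per_loop, _ = loop_contact_change(loops, np.array([10.0, 10.0]),
                                      np.array([10.0, 5.0]), regions,
                                      classes)
    # equal contacts -> log2fc 0; unclassified-only loop excluded
    assert per_loop["log2fc"].tolist() == [0.0]
    assert per_loop["group"].tolist() == ["decreased"]


def test_loop_contacts_must_be_positive():
    loops = [LoopRecord(GenomicInterval("chr1", 0, 100),
                        GenomicInterval("chr1", 500, 600), "a")]
    with pytest.raises(ValueError):
        loop_contact_change(loops, np.array([0.0]), np.array([1.0]),
                            [GenomicInterval("chr1", 0, 100)],
                            np.array(["control"]))


def test_tad_distance_examples():
    boundaries = [GenomicInterval("chr1", 900, 1100)]
    out = tad_distance([("chr1", 1000), ("chr1", 1500), ("chr2", 5)],
                       ["control", "increased", "control"], boundaries)
    assert out["distance"].tolist() == [0.0, 500.0]  # chr2 excluded
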