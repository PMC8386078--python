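"""PWM scanning with exact p-values, summit-motif geometry, Fisher
enrichment and tandem-site detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, hypergeom

from chromshift.intervals import GenomicInterval, Summit
from chromshift.motifs import (PWM, enrichment_volcano,
                               nearest_motif_distance, orient_summits,
                               pairwise_motif_distance, read_pwms,
                               regions_with_hit, scan_pwm, tandem_sites,
                               write_pwms)
from chromshift.stats import fisher_exact_two_sided, odds_ratio

UNIFORM_BG = np.full(4, 0.25)


def _det_pwm(consensus, major=0.97):
    minor = (1 - major) / 3
    mat = np.full((len(consensus), 4), minor)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = major
    return PWM(consensus, mat, UNIFORM_BG)


def test_consensus_scan_finds_both_strands():
    pwm = _det_pwm("ACG")
    hits = scan_pwm({"chr1": "TTACGTT"}, pwm, threshold_p=2e-2)
    plus = hits.loc[hits["strand"] == "+"]
    minus = hits.loc[hits["strand"] == "-"]
    assert [(int(r.start), int(r.end)) for r in plus.itertuples()] == [(2, 5)]
    # reverse complement of ACG is CGT, present at [3, 6)
    assert [(int(r.start), int(r.end)) for r in minus.itertuples()] == [(3, 6)]


def test_uniform_pwm_produces_no_hits():
    pwm = PWM("flat", np.full((6, 4), 0.25), UNIFORM_BG)
    hits = scan_pwm({"chr1": "ACGTACGTACGT" * 5}, pwm, 1e-4)
    assert len(hits) == 0


def test_exact_pvalues_match_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    mat = rng.dirichlet(np.ones(4), size=3)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    pwm = PWM("rand3", mat, bg)
    lo = pwm.log_odds
    scores, probs = [], []
    for window in itertools.product(range(4), repeat=3):
        scores.append(sum(lo[i, b] for i, b in enumerate(window)))
        probs.append(np.prod([bg[b] for b in window]))
    scores, probs = np.array(scores), np.array(probs)
    for s in np.quantile(scores, [0.0, 0.25, 0.5, 0.75, 1.0]):
        brute = probs[scores >= s - 5e-4].sum()
        assert pwm.score_pvalue(np.array([s]))[0] == pytest.approx(brute,
                                                                   abs=1e-9)


def test_scan_of_reverse_complement_is_mirror_image():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
    pwm = _det_pwm("ACGTA", major=0.85)
    fwd = scan_pwm({"c": seq}, pwm, 1e-2)
    rev = scan_pwm({"c": rc}, pwm, 1e-2)
    flip = {"+": "-", "-": "+"}
    mirrored = sorted(
        (len(seq) - int(r.end), len(seq) - int(r.start), flip[r.strand])
        for r in fwd.itertuples()
    )
    got = sorted((int(r.start), int(r.end), r.strand) for r in rev.itertuples())
    assert got == mirrored


def test_n_bases_score_as_background():
    pwm = _det_pwm("ACGT")
    clean = scan_pwm({"c": "AAACGTAAA"}, pwm, 5e-2)
    with_n = scan_pwm({"c": "AAACGNAAA"}, pwm, 5e-2)
    assert len(clean) >= 1
    # the N position contributes log-odds 0, lowering the score
    if len(with_n):
        assert with_n["score"].max() < clean["score"].max()


def test_pwm_file_roundtrip(tmp_path):
    pwm = _det_pwm("ACGTAC")
    write_pwms([pwm], tmp_path / "m.pwm")
    back = read_pwms(str(tmp_path / "m.pwm"))
    assert back[0].motif_id == pwm.motif_id
    np.testing.assert_allclose(back[0].matrix, pwm.matrix, atol=1e-6)


def _hits(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "center", "score", "p"]
    )


def test_nearest_distance_examples():
    hits = _hits([("chr1", 95, 105, "+", 100, 8.0, 1e-5),
                  ("chr1", 295, 305, "+", 300, 8.0, 1e-5)])
    summits = [Summit("chr1", 100), Summit("chr1", 110), Summit("chr2", 5)]
    out = nearest_motif_distance(summits, hits)
    assert out["distance"].tolist() == [0, 10]
    assert out["log10_distance"].iloc[0] == 0.0
    assert len(out) == 2  # chr2 summit excluded


def test_orientation_tie_broken_by_score():
    hits = _hits([("chr1", 85, 95, "-", 90, 8.1, 1e-5),
                  ("chr1", 105, 115, "+", 110, 5.2, 1e-5)])
    out = orient_summits([Summit("chr1", 100)], hits)
    assert bool(out["flip"].iloc[0]) is True  # equidistant, higher score is '-'


def test_single_plus_hit_no_flip():
    hits = _hits([("chr1", 85, 95, "+", 90, 8.1, 1e-5)])
    out = orient_summits([Summit("chr1", 100)], hits)
    assert bool(out["flip"].iloc[0]) is False


def test_enrichment_reproduces_published_tandem_site_table():
    """1244/8042 increased DARs vs 204/8440 control NFRs -> OR 7.39."""
    a, n1, c, n2 = 1244, 8042, 204, 8440
    or_ = odds_ratio(a, n1 - a, c, n2 - c)
    assert or_ == pytest.approx(7.39, abs=0.01)


def test_enrichment_volcano_counts_and_fisher():
    regions_cls = [GenomicInterval("chr1", i * 100, i * 100 + 50)
                   for i in range(10)]
    regions_other = [GenomicInterval("chr2", i * 100, i * 100 + 50)
                     for i in range(10)]
    # hits in 3 of 10 class regions, 1 of 10 others
    rows = [("chr1", i * 100 + 10, i * 100 + 20, "+", i * 100 + 15, 5.0, 1e-5)
            for i in range(3)]
    rows += [("chr2", 10, 20, "+", 15, 5.0, 1e-5)]
    out = enrichment_volcano(regions_cls, regions_other, {"m": _hits(rows)})
    row = out.iloc[0]
    assert (row["a"], row["b"], row["c"], row["d"]) == (3, 7, 1, 9)
    assert row["odds_ratio"] == pytest.approx(27 / 7)
    assert row["p"] == pytest.approx(
        fisher_exact([[3, 7], [1, 9]]).pvalue, abs=1e-12)


def test_identical_frequencies_or_one():
    assert odds_ratio(5, 5, 5, 5) == 1.0


def test_fisher_matches_enumeration_small_margins():
    rng = np.random.default_rng(8)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        mine = fisher_exact_two_sided(a, b, c, d)[0]
        ref = fisher_exact([[a, b], [c, d]]).pvalue
        assert mine == pytest.approx(ref, abs=1e-9)


def test_or_invariant_to_double_swap():
    a, b, c, d = 3, 11, 7, 2
    assert odds_ratio(a, b, c, d) == pytest.approx(odds_ratio(d, c, b, a))


def test_tandem_site_detection():
    hits = _hits([("chr1", 95, 105, "+", 100, 5, 1e-5),
                  ("chr1", 125, 135, "-", 130, 5, 1e-5),
                  ("chr1", 495, 505, "+", 500, 5, 1e-5),
                  ("chr1", 595, 605, "+", 600, 5, 1e-5)])
    out = tandem_sites(hits, max_gap=35)
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (95, 135)


def test_tandem_run_of_three_spans_all():
    hits = _hits([("chr1", 95, 105, "+", 100, 5, 1e-5),
                  ("chr1", 125, 135, "+", 130, 5, 1e-5),
                  ("chr1", 155, 165, "+", 160, 5, 1e-5)])
    out = tandem_sites(hits, max_gap=35)
    assert len(out) == 1 and (out[0].start, out[0].end) == (95, 165)


def test_pairwise_distance_normalized():
    region = [GenomicInterval("chr1", 0, 1000)]
    a = _hits([("chr1", 95, 105, "+", 100, 5, 1e-5)])
    b = _hits([("chr1", 295, 305, "+", 300, 5, 1e-5)])
    out = pairwise_motif_distance(region, a, b)
    assert out["normalized_distance"].iloc[0] == pytest.approx(0.2)
    same = pairwise_motif_distance(region, a, a)
    assert same["normalized_distance"].iloc[0] == 0.0
    missing = pairwise_motif_distance(
        [GenomicInterval("chr1", 2000, 3000)], a, b)
    assert len(missing) == 0


def test_regions_with_hit_requires_one_bp_overlap():
    regions = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]
    hits = _hits([("chr1", 195, 205, "+", 200, 5, 1e-5)])
    mask = regions_with_hit(regions, hits)
    assert mask.tolist() == [True, False]
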