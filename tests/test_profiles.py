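"""Profile matrices, k-means heatmap clustering, peak-shape calls,
orientation bias and footprint aggregation."""

import numpy as np
import pytest

from chromshift.profiles import (ProfileMatrix, classify_shape,
                                 extract_matrix, footprint, kmeans_profiles,
                                 orientation_bias)
from chromshift.track import SignalTrack


def _flat_track(value=2.0, length=10_000):
    return SignalTrack({"chr1": (np.array([0]), np.array([length]),
                                 np.array([value]))})


def test_flat_track_gives_constant_bins():
    mat = extract_matrix(_flat_track(2.0), [("chr1", 5000)], 200, 10)
    np.testing.assert_allclose(mat.matrix, 2.0)
    assert mat.matrix.shape == (1, 40)


def test_delta_bump_maximal_at_center():
    tr = SignalTrack({"chr1": (np.array([4995]), np.array([5005]),
                               np.array([10.0]))})
    mat = extract_matrix(tr, [("chr1", 5000)], 100, 10)
    prof = mat.matrix[0]
    assert prof.argmax() in (9, 10)


def test_oriented_extraction_of_mirror_pair_identical_rows():
    # bump left of anchor 1, mirrored bump right of anchor 2
    tr = SignalTrack({"chr1": (np.array([900, 3050]), np.array([950, 3100]),
                               np.array([5.0, 5.0]))})
    mat = extract_matrix(tr, [("chr1", 1000), ("chr1", 3000)], 200, 10,
                         oriented=True, flip=np.array([False, True]))
    np.testing.assert_allclose(mat.matrix[0], mat.matrix[1])


def test_extract_matrix_linear_in_track():
    tr = SignalTrack({"chr1": (np.array([100, 400]), np.array([300, 600]),
                               np.array([1.0, 4.0]))})
    m1 = extract_matrix(tr, [("chr1", 350)], 300, 20).matrix
    m3 = extract_matrix(tr.scaled(3.0), [("chr1", 350)], 300, 20).matrix
    np.testing.assert_allclose(m3, 3 * m1)


def test_edge_anchor_zero_padded():
    mat = extract_matrix(_flat_track(1.0), [("chr1", 50)], 200, 10)
    row = mat.matrix[0]
    assert row[:10].sum() == 0 and row[-1] == 1.0


def _two_shape_matrix():
    x = np.arange(50)
    peak_left = np.exp(-0.5 * ((x - 15) / 3.0) ** 2)
    peak_right = np.exp(-0.5 * ((x - 35) / 3.0) ** 2)
    rows = [peak_left * 5] * 10 + [peak_right * 3] * 10
    return ProfileMatrix([("chr1", i) for i in range(20)], 250, 10,
                         np.array(rows), np.zeros(20, dtype=bool))


def test_kmeans_separates_two_shapes_and_is_deterministic():
    mat = _two_shape_matrix()
    labels1, means = kmeans_profiles(mat, 2, seed=0)
    labels2, _ = kmeans_profiles(mat, 2, seed=0)
    np.testing.assert_array_equal(labels1, labels2)
    assert len(set(labels1[:10])) == 1 and len(set(labels1[10:])) == 1
    assert labels1[0] != labels1[10]
    # labels ordered by descending mean signal: the amp-5 cluster is 0
    assert labels1[0] == 0


def test_kmeans_k1_mean_profile():
    mat = _two_shape_matrix()
    labels, means = kmeans_profiles(mat, 1, seed=0)
    assert set(labels) == {0}
    np.testing.assert_allclose(means[0], mat.matrix.mean(axis=0))


def test_kmeans_rejects_k_larger_than_rows():
    mat = _two_shape_matrix()
    with pytest.raises(ValueError):
        kmeans_profiles(mat, 21)


def _gauss(x, mu, s):
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def test_shape_classification():
    x = np.arange(-250, 250, 10)
    double = _gauss(x, -100, 30) + _gauss(x, 100, 30)
    single = _gauss(x, 0, 40)
    assert classify_shape(double, min_gap_bins=5) == "double"
    assert classify_shape(single, min_gap_bins=5) == "single"
    assert classify_shape(np.zeros(50)) == "flat"


def test_shape_invariant_to_reversal():
    x = np.arange(-250, 250, 10)
    asym = _gauss(x, -120, 25) + 0.8 * _gauss(x, 90, 25)
    assert classify_shape(asym) == classify_shape(asym[::-1])


def _matrix(rows):
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[1]
    return ProfileMatrix([("chr1", i) for i in range(len(rows))],
                         n * 5, 10, rows, np.zeros(len(rows), dtype=bool))


def test_orientation_bias_symmetric_profiles():
    rows = np.tile(np.concatenate([np.ones(10), np.ones(10)]), (9, 1))
    med, p, _ = orientation_bias(_matrix(rows))
    assert med == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_orientation_bias_all_upstream():
    rows = np.tile(np.concatenate([np.ones(10), np.zeros(10)]), (9, 1))
    med, p, _ = orientation_bias(_matrix(rows))
    assert med >= 1e6  # capped sentinel
    assert p < 0.01


def test_footprint_uniform_ratio_one():
    tr = _flat_track(3.0)
    import pandas as pd

    hits = pd.DataFrame(
        {"chrom": ["chr1"], "start": [4995], "end": [5005], "strand": ["+"],
         "center": [5000], "score": [5.0], "p": [1e-5]}
    )
    prof, ratio = footprint(tr, hits, motif_width=10, half_width=50)
    assert ratio == pytest.approx(1.0)
    np.testing.assert_allclose(prof, 3.0)


def test_footprint_aggregation_additivity():
    """N identical windows sum to N x the single-window profile."""
    import pandas as pd

    tr = SignalTrack({"chr1": (np.arange(0, 10_000, 100),
                               np.arange(0, 10_000, 100) + 50,
                               np.tile([2.0], 100))})
    one = pd.DataFrame({"chrom": ["chr1"], "start": [995], "end": [1005],
                        "strand": ["+"], "center": [1000], "score": [1.0],
                        "p": [1e-5]})
    three = pd.concat([one] * 3, ignore_index=True)
    p1, _ = footprint(tr, one, motif_width=10, half_width=40)
    p3, _ = footprint(tr, three, motif_width=10, half_width=40)
    np.testing.assert_allclose(p3, 3 * p1)


def test_footprint_protected_core(study, class_map, refined_summits,
                                  ctcf_hits):
    """Planted bound CTCF motifs show a central dip; the protection
    ratio exceeds 1.5."""
    import pandas as pd

    from chromshift.motifs import _centers_in, _hits_by_chrom

    dec = [r for r, _ in refined_summits if class_map[r.name] == "decreased"]
    by_chrom = _hits_by_chrom(ctcf_hits)
    keep = []
    for r in dec:
        sub = by_chrom.get(r.chrom)
        centers = _centers_in(sub, r)
        keep.append(sub.loc[sub["center"].isin(centers)])
    hits = pd.concat(keep, ignore_index=True)
    _, ratio = footprint(study.insertion, hits, motif_width=19,
                         half_width=100)
    assert ratio > 1.5


def test_footprint_unbound_motif_flat(study, class_map, decoy_hits):
    """Decoy motifs in control regions sit in uniform insertion
    background: ratio about 1."""
    import pandas as pd

    from chromshift.motifs import _centers_in, _hits_by_chrom

    ctrl = [iv for iv in study.regions if class_map[iv.name] == "control"]
    by_chrom = _hits_by_chrom(decoy_hits)
    keep = []
    for r in ctrl:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            continue
        centers = _centers_in(sub, r)
        keep.append(sub.loc[sub["center"].isin(centers)])
    hits = pd.concat(keep, ignore_index=True)
    _, ratio = footprint(study.insertion, hits, motif_width=10,
                         half_width=100)
    assert ratio == pytest.approx(1.0, abs=0.1)
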