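"""Signal matrices around anchors, heatmap k-means, peak-shape calls,
orientation bias, and Tn5 footprint aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .stats import sign_test_p
from .track import SignalTrack

logger = logging.getLogger(__name__)

RATIO_CAP = 1e6  # sentinel for all-signal-on-one-side rows


@dataclass
class ProfileMatrix:
    """Mean signal per bin around ordered anchors.

    ``anchors`` is a list of (chrom, pos) pairs; rows of ``matrix`` align
    1:1 with anchors. ``flipped`` records which rows were reversed during
    oriented extraction.
    """

    anchors: list[tuple[str, int]]
    half_width: int
    bin_size: int
    matrix: np.ndarray
    flipped: np.ndarray

    def __post_init__(self) -> None:
        n_bins = 2 * self.half_width // self.bin_size
        if self.matrix.shape != (len(self.anchors), n_bins):
            raise ValueError("matrix shape inconsistent with anchors/window")

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers relative to the anchor (bp)."""
        edges = np.arange(-self.half_width, self.half_width + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0) if len(self.anchors) else np.zeros(
            2 * self.half_width // self.bin_size)


def extract_matrix(
    track: SignalTrack,
    anchors: list[tuple[str, int]],
    half_width: int,
    bin_size: int,
    oriented: bool = False,
    flip: np.ndarray | None = None,
) -> ProfileMatrix:
    """Mean track value per bin around each anchor.

    With ``oriented=True``, rows whose ``flip`` flag is set are reversed
    so that "upstream of the motif" is always on the left. Windows
    reaching past position 0 are padded with zeros (counted in the log).
    """
    if 2 * half_width % bin_size != 0:
        raise ValueError("window must be a whole number of bins")
    n_bins = 2 * half_width // bin_size
    if oriented:
        if flip is None:
            raise ValueError("oriented extraction requires flip flags")
        flip = np.asarray(flip, dtype=bool)
        if len(flip) != len(anchors):
            raise ValueError("flip flags must align with anchors")
    else:
        flip = np.zeros(len(anchors), dtype=bool)
    mat = np.zeros((len(anchors), n_bins))
    rel = np.arange(-half_width, half_width + 1, bin_size)
    n_edge = 0
    for chrom in sorted({c for c, _ in anchors}):
        idx = [i for i, (c, _) in enumerate(anchors) if c == chrom]
        pos = np.array([anchors[i][1] for i in idx])
        edges = pos[:, None] + rel[None, :]
        n_edge += int(np.sum(edges[:, 0] < 0))
        mat[idx, :] = track.window_means(chrom, edges)
    if n_edge:
        logger.info("extract_matrix: %d anchors near chromosome edge "
                    "(zero-padded)", n_edge)
    mat[flip] = mat[flip, ::-1]
    return ProfileMatrix(list(anchors), half_width, bin_size, mat, flip)


def kmeans_profiles(
    matrix: ProfileMatrix, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean k-means on row-max-normalized profiles.

    Rows with an all-zero profile are dropped from the fit and labelled
    -1. Cluster labels are renumbered by descending cluster mean signal
    (label 0 = strongest). Returns (labels, cluster mean profiles) where
    the means are of the raw (unnormalized) rows.
    """
    X = matrix.matrix
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    rowmax = X.max(axis=1)
    ok = rowmax > 0
    Xn = X[ok] / rowmax[ok, None]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(Xn)
    # renumber by descending mean raw signal
    strength = np.array([
        X[ok][raw_labels == c].mean() if np.any(raw_labels == c) else -np.inf
        for c in range(k)
    ])
    order = np.argsort(-strength, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = np.full(X.shape[0], -1, dtype=int)
    labels[ok] = remap[raw_labels]
    means = np.stack([
        X[labels == c].mean(axis=0) if np.any(labels == c) else np.zeros(X.shape[1])
        for c in range(k)
    ])
    return labels, means


def classify_shape(
    mean_profile: np.ndarray,
    min_prominence_frac: float = 0.3,
    min_gap_bins: int = 5,
    noise_floor: float = 1e-12,
) -> str:
    """Call a mean profile single-, double-summited, or flat.

    Local maxima must have prominence >= min_prominence_frac x global
    max; two or more maxima separated by >= min_gap_bins give "double".
    """
    y = np.asarray(mean_profile, dtype=float)
    top = y.max() if y.size else 0.0
    if top <= noise_floor:
        return "flat"
    # pad with -inf so maxima at the array ends are still counted
    padded, _ = find_peaks(
        np.concatenate([[-np.inf], y, [-np.inf]]),
        prominence=min_prominence_frac * top,
        distance=max(min_gap_bins, 1),
    )
    n = len(padded)
    if n >= 2:
        return "double"
    if n == 1:
        return "single"
    return "flat"


def orientation_bias(matrix: ProfileMatrix) -> tuple[float, float, pd.DataFrame]:
    """Upstream/downstream signal ratio per row of an oriented matrix.

    Returns (median ratio, two-sided sign-test p, per-row table). Rows
    with signal on only one side get the capped sentinel ratio; rows with
    no signal at all are excluded.
    """
    n_bins = matrix.matrix.shape[1]
    up = matrix.matrix[:, : n_bins // 2].sum(axis=1)
    down = matrix.matrix[:, n_bins // 2 :].sum(axis=1)
    keep = (up + down) > 0
    with np.errstate(divide="ignore"):
        ratio = np.where(down[keep] > 0, up[keep] / np.maximum(down[keep], 1e-300),
                         RATIO_CAP)
    ratio = np.minimum(ratio, RATIO_CAP)
    n_pos = int(np.sum(ratio > 1))
    n_neg = int(np.sum(ratio < 1))
    p = sign_test_p(n_pos, n_neg)
    med = float(np.median(ratio)) if ratio.size else float("nan")
    table = pd.DataFrame({"row": np.flatnonzero(keep), "ratio": ratio})
    return med, p, table


def footprint(
    insertion_track: SignalTrack,
    hits: pd.DataFrame,
    motif_width: int,
    half_width: int = 100,
) -> tuple[np.ndarray, float]:
    """Aggregate per-base insertion counts over motif-centered,
    strand-oriented windows.

    Returns (aggregate profile of length 2*half_width + 1, protection
    ratio). The protection ratio is the larger of the two flanking summit
    values divided by the mean over the central motif-width span; > 1
    means the motif core is protected from Tn5 insertion.
    """
    n = 2 * half_width + 1
    agg = np.zeros(n)
    rel = np.arange(-half_width, half_width + 1)
    count = 0
    for chrom, sub in hits.groupby("chrom"):
        centers = sub["center"].to_numpy()
        strands = sub["strand"].to_numpy()
        for cpos, strand in zip(centers, strands):
            vals = insertion_track.values_at(chrom, cpos + rel)
            agg += vals[::-1] if strand == "-" else vals
            count += 1
    if count == 0:
        return agg, float("nan")
    half_motif = motif_width // 2
    core = slice(half_width - half_motif, half_width + half_motif + 1)
    core_mean = float(np.mean(agg[core]))
    left = agg[: half_width - half_motif]
    right = agg[half_width + half_motif + 1 :]
    flank_summit = max(
        float(left.max()) if left.size else 0.0,
        float(right.max()) if right.size else 0.0,
    )
    ratio = flank_summit / core_mean if core_mean > 0 else float("inf")
    return agg, ratio
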