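"""PWM scanning and motif-summit geometry.

Scanning scores every window on both strands with a log2 odds score
(pseudo-probability-adjusted matrix over a background model) and converts
scores to match p-values through the exact score distribution under the
background, computed by dynamic programming over discretized scores
(1e-3 bins). Hits are windows with p <= a threshold (default 1e-4).

Bulk hit sets are pandas DataFrames with columns
``chrom, start, end, strand, center, score, p`` where
``center = floor((start + end) / 2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Summit
from .stats import fisher_exact_two_sided, odds_ratio

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_SCORE_BIN = 1e-3

HIT_COLUMNS = ["chrom", "start", "end", "strand", "center", "score", "p"]


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        HIT_COLUMNS, [str, int, int, str, int, float, float])})


@dataclass
class PWM:
    """Position weight matrix with background and pseudo-probability."""

    motif_id: str
    matrix: np.ndarray  # length x 4 base probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 1e-4

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be length x 4")
        if len(self) < 3:
            raise ValueError("PWM length must be >= 3")
        probs = self.probs
        if np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("PWM columns must sum to 1 after pseudo-count")
        self._dp_cache: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Pseudo-probability-adjusted matrix (rows sum to 1)."""
        return (self.matrix + self.pseudo * self.background[None, :]) / (
            1.0 + self.pseudo
        )

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.pseudo)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    # -- exact score distribution under the background ------------------

    def _dp_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(units, tail) where ``tail[u]`` = P(score >= u * bin + offset)
        under the background; units are integer discretized scores with
        per-position minima subtracted."""
        if self._dp_cache is not None:
            return self._dp_cache
        lo_units = np.round(self.log_odds / _SCORE_BIN).astype(np.int64)
        mins = lo_units.min(axis=1)
        shifted = lo_units - mins[:, None]
        total_range = int(shifted.max(axis=1).sum())
        dist = np.zeros(total_range + 1)
        dist[0] = 1.0
        width = 0
        for j in range(len(self)):
            new = np.zeros_like(dist)
            for b in range(4):
                u = shifted[j, b]
                new[u : u + width + 1] += self.background[b] * dist[: width + 1]
            dist = new
            width += int(shifted[j].max())
        tail = np.cumsum(dist[::-1])[::-1]
        self._dp_cache = (mins, np.minimum(tail, 1.0))
        return self._dp_cache

    def score_pvalue(self, scores: np.ndarray) -> np.ndarray:
        """Exact P(background window scores >= observed) per score."""
        mins, tail = self._dp_tables()
        units = np.round(np.asarray(scores) / _SCORE_BIN).astype(np.int64)
        units = units - int(mins.sum())
        units = np.clip(units, 0, len(tail) - 1)
        return tail[units]

    def score_threshold(self, threshold_p: float) -> float:
        """Smallest log-odds score whose exact p-value is <= threshold_p."""
        mins, tail = self._dp_tables()
        idx = np.searchsorted(-tail, -threshold_p, side="left")
        if idx >= len(tail):
            return np.inf
        return (idx + int(mins.sum())) * _SCORE_BIN


def read_pwms(path: str, background: np.ndarray | None = None,
              pseudo: float = 1e-4) -> list[PWM]:
    """Read the block PWM text format: '>id' header, one row per motif
    position with 4 whitespace-separated columns (A C G T)."""
    pwms: list[PWM] = []
    name = None
    rows: list[list[float]] = []
    bg = np.full(4, 0.25) if background is None else np.asarray(background)

    def flush():
        if name is not None:
            pwms.append(PWM(name, np.array(rows), bg.copy(), pseudo))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PWM row must have 4 columns: {line!r}")
                rows.append(vals)
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Sum of per-position log-odds over each window; N bases (code 4)
    contribute 0 (background odds)."""
    L = log_odds.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.zeros(0)
    lut = np.concatenate([log_odds, np.zeros((L, 1))], axis=1)  # N column
    acc = np.zeros(n_win)
    for j in range(L):
        acc += lut[j, codes[j : j + n_win]]
    return acc


def encode_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def scan_pwm(
    sequences: dict[str, str],
    pwm: PWM,
    threshold_p: float = 1e-4,
) -> pd.DataFrame:
    """Scan both strands of every sequence; hits are windows with exact
    match p <= threshold_p."""
    L = len(pwm)
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    cut = pwm.score_threshold(threshold_p)
    frames = []
    for chrom, seq in sequences.items():
        if len(seq) < L:
            continue
        codes = encode_sequence(seq)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _window_scores(codes, lo)
            idx = np.flatnonzero(scores >= cut)
            if idx.size == 0:
                continue
            starts = idx
            ends = idx + L
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "strand": strand,
                        "center": (starts + ends) // 2,
                        "score": scores[idx],
                        "p": pwm.score_pvalue(scores[idx]),
                    }
                )
            )
    if not frames:
        return _empty_hits()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(
        drop=True
    )


# -- summit-motif geometry ---------------------------------------------


def _hits_by_chrom(hits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        str(chrom): sub.sort_values("center", kind="stable").reset_index(drop=True)
        for chrom, sub in hits.groupby("chrom")
    }


def nearest_motif_distance(
    summits: list[Summit], hits: pd.DataFrame
) -> pd.DataFrame:
    """Per-summit distance (bp) to the nearest hit center on the same
    chromosome, plus log10(d + 1). Summits on chromosomes without hits
    are excluded (and counted in the log)."""
    by_chrom = _hits_by_chrom(hits)
    rows = []
    n_excluded = 0
    for i, s in enumerate(summits):
        sub = by_chrom.get(s.chrom)
        if sub is None or len(sub) == 0:
            n_excluded += 1
            continue
        centers = sub["center"].to_numpy()
        j = int(np.searchsorted(centers, s.pos))
        cands = []
        if j > 0:
            cands.append(abs(s.pos - int(centers[j - 1])))
        if j < len(centers):
            cands.append(abs(s.pos - int(centers[j])))
        d = min(cands)
        rows.append({"summit_index": i, "chrom": s.chrom, "pos": s.pos,
                     "distance": d, "log10_distance": float(np.log10(d + 1))})
    if n_excluded:
        logger.info("nearest_motif_distance: %d summits excluded "
                    "(no hit on chromosome)", n_excluded)
    return pd.DataFrame(rows, columns=["summit_index", "chrom", "pos",
                                       "distance", "log10_distance"])


def orient_summits(summits: list[Summit], hits: pd.DataFrame) -> pd.DataFrame:
    """Assign each summit the strand of its nearest hit; distance ties are
    broken by higher score, then by leftmost start (then '+' strand).
    Returns a table with ``flip`` True for '-' strand assignments; summits
    with no hit on their chromosome are dropped."""
    by_chrom = _hits_by_chrom(hits)
    rows = []
    for i, s in enumerate(summits):
        sub = by_chrom.get(s.chrom)
        if sub is None or len(sub) == 0:
            continue
        centers = sub["center"].to_numpy()
        d = np.abs(centers - s.pos)
        dmin = d.min()
        cand = sub.loc[d == dmin]
        cand = cand.sort_values(
            ["score", "start", "strand"], ascending=[False, True, True],
            kind="stable",
        )
        best = cand.iloc[0]
        rows.append(
            {
                "summit_index": i,
                "chrom": s.chrom,
                "pos": s.pos,
                "motif_strand": best["strand"],
                "motif_score": float(best["score"]),
                "distance": int(dmin),
                "flip": best["strand"] == "-",
            }
        )
    return pd.DataFrame(rows, columns=["summit_index", "chrom", "pos",
                                       "motif_strand", "motif_score",
                                       "distance", "flip"])


# -- enrichment ---------------------------------------------------------


def regions_with_hit(
    regions: list[GenomicInterval], hits: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: region overlaps >= 1 hit interval by >= 1 bp."""
    mask = np.zeros(len(regions), dtype=bool)
    for chrom, sub in hits.groupby("chrom"):
        starts = np.sort(sub["start"].to_numpy())
        ends_sorted_by_start = sub.sort_values("start")["end"].to_numpy()
        max_end = np.maximum.accumulate(ends_sorted_by_start)
        for i, r in enumerate(regions):
            if r.chrom != chrom or mask[i]:
                continue
            hi = int(np.searchsorted(starts, r.end, side="left"))
            if hi == 0:
                continue
            # any of the first hi hits ends beyond region start?
            if max_end[hi - 1] > r.start:
                lo = int(np.searchsorted(max_end[:hi], r.start, side="right"))
                if np.any(ends_sorted_by_start[lo:hi] > r.start):
                    mask[i] = True
    return mask


def enrichment_volcano(
    class_regions: list[GenomicInterval],
    other_regions: list[GenomicInterval],
    hits_per_motif: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per motif: 2x2 table of (region has >= 1 hit) x (class vs other),
    sample odds ratio and two-sided Fisher p; rows sorted by p."""
    rows = []
    for motif_id, hits in hits_per_motif.items():
        a = int(regions_with_hit(class_regions, hits).sum())
        b = len(class_regions) - a
        c = int(regions_with_hit(other_regions, hits).sum())
        d = len(other_regions) - c
        p = float(fisher_exact_two_sided(a, b, c, d)[0])
        rows.append(
            {"motif": motif_id, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds_ratio(a, b, c, d), "p": p}
        )
    return (
        pd.DataFrame(rows, columns=["motif", "a", "b", "c", "d", "odds_ratio", "p"])
        .sort_values("p", kind="stable")
        .reset_index(drop=True)
    )


def tandem_sites(hits: pd.DataFrame, max_gap: int = 35) -> list[GenomicInterval]:
    """Maximal runs of >= 2 hits with successive center gaps <= max_gap
    (any strand combination), emitted as the spanning interval."""
    out: list[GenomicInterval] = []
    for chrom, sub in hits.groupby("chrom"):
        sub = sub.sort_values(["center", "start"], kind="stable")
        centers = sub["center"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(centers) == 0:
            continue
        run_start = 0
        for i in range(1, len(centers) + 1):
            if i == len(centers) or centers[i] - centers[i - 1] > max_gap:
                if i - run_start >= 2:
                    out.append(
                        GenomicInterval(
                            str(chrom),
                            int(starts[run_start:i].min()),
                            int(ends[run_start:i].max()),
                            name=f"2xCTS_n{i - run_start}",
                        )
                    )
                run_start = i
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def pairwise_motif_distance(
    regions: list[GenomicInterval],
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
) -> pd.DataFrame:
    """Per region, minimum |centerA - centerB| among hit pairs whose
    centers lie inside the region, normalized to region length. Regions
    lacking either motif are excluded (counted in the log)."""
    a_by = _hits_by_chrom(hits_a)
    b_by = _hits_by_chrom(hits_b)
    rows = []
    n_excluded = 0
    for i, r in enumerate(regions):
        ca = _centers_in(a_by.get(r.chrom), r)
        cb = _centers_in(b_by.get(r.chrom), r)
        if ca.size == 0 or cb.size == 0:
            n_excluded += 1
            continue
        d = int(np.min(np.abs(ca[:, None] - cb[None, :])))
        rows.append(
            {"region_index": i, "distance": d,
             "normalized_distance": d / len(r)}
        )
    if n_excluded:
        logger.info("pairwise_motif_distance: %d regions lacked a hit of "
                    "one motif", n_excluded)
    return pd.DataFrame(rows, columns=["region_index", "distance",
                                       "normalized_distance"])


def _centers_in(sub: pd.DataFrame | None, region: GenomicInterval) -> np.ndarray:
    if sub is None:
        return np.zeros(0, dtype=int)
    centers = sub["center"].to_numpy()
    lo = np.searchsorted(centers, region.start, side="left")
    hi = np.searchsorted(centers, region.end, side="left")
    return centers[lo:hi]
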