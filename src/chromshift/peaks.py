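"""Reference nucleosome-free regions, summit refinement, fragment counting.

The reference set is built with a reproducibility rule over per-group
peak calls: a peak region is kept iff it was called stringently
(q <= 0.05) in at least one group and at least leniently (q <= 0.5) in
every other group; retained regions from all groups are then
interval-merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, IntervalIndex, Summit, merge_intervals
from .io import NarrowPeak, narrowpeak_qvalue
from .track import SignalTrack

logger = logging.getLogger(__name__)


@dataclass
class NFRRecord:
    """A reference NFR with refined summit and per-sample counts."""

    interval: GenomicInterval
    summit: Summit | None = None
    counts: np.ndarray | None = None
    group_presence: dict[str, str] = field(default_factory=dict)


def build_reference_nfrs(
    group_peaks: dict[str, list[NarrowPeak]],
    stringent_q: float = 0.05,
    lenient_q: float = 0.5,
) -> list[GenomicInterval]:
    """Reproducible reference regions from per-group peak sets.

    Retention is decided per peak by overlap with the other groups'
    peaks: stringent in its own group (q <= stringent_q) and overlapped
    by a lenient call (q <= lenient_q) in every other group. Symmetric in
    group order; the retained peaks are interval-merged.
    """
    if len(group_peaks) < 2:
        raise ValueError("need >= 2 groups to assess reproducibility")
    lenient_idx: dict[str, IntervalIndex] = {}
    for grp, peaks in group_peaks.items():
        lenient = [p.interval for p in peaks if narrowpeak_qvalue(p) <= lenient_q]
        lenient_idx[grp] = IntervalIndex(lenient)
    retained: list[GenomicInterval] = []
    for grp, peaks in group_peaks.items():
        others = [g for g in group_peaks if g != grp]
        for p in peaks:
            if narrowpeak_qvalue(p) > stringent_q:
                continue
            if all(lenient_idx[g].overlapping(p.interval) for g in others):
                retained.append(p.interval)
    return merge_intervals(retained)


def refine_summits(
    reference: list[GenomicInterval],
    replicate_summits: list[Summit],
    min_separation: int = 500,
) -> tuple[list[tuple[GenomicInterval, Summit]], dict[str, int]]:
    """Pick, per reference region, the replicate summit closest to the
    region center (ties -> smaller position), then drop every pair of
    chosen summits closer than ``min_separation`` (both members removed).

    Returns (kept (region, summit) pairs, log counts).
    """
    index = IntervalIndex(reference)
    assigned: dict[int, list[int]] = {}
    for si, s in enumerate(replicate_summits):
        for ri in index.containing_point(s.chrom, s.pos):
            assigned.setdefault(ri, []).append(si)
    chosen: list[tuple[GenomicInterval, Summit]] = []
    n_no_summit = 0
    for ri, region in enumerate(reference):
        cand = assigned.get(ri)
        if not cand:
            n_no_summit += 1
            continue
        center = region.center
        best = min(
            cand,
            key=lambda si: (abs(replicate_summits[si].pos - center),
                            replicate_summits[si].pos),
        )
        s = replicate_summits[best]
        chosen.append((region, Summit(s.chrom, s.pos, region)))
    # cross-region proximity filter: both members of a too-close pair go
    drop = np.zeros(len(chosen), dtype=bool)
    order = sorted(range(len(chosen)),
                   key=lambda i: (chosen[i][1].chrom, chosen[i][1].pos))
    for a, b in zip(order, order[1:]):
        sa, sb = chosen[a][1], chosen[b][1]
        if sa.chrom == sb.chrom and abs(sb.pos - sa.pos) < min_separation:
            drop[a] = drop[b] = True
    kept = [pair for i, pair in enumerate(chosen) if not drop[i]]
    log = {
        "regions": len(reference),
        "no_summit": n_no_summit,
        "too_close_removed": int(drop.sum()),
        "kept": len(kept),
    }
    if n_no_summit:
        logger.info("refine_summits: %d regions had no replicate summit",
                    n_no_summit)
    return kept, log


def count_fragments(
    reference: list[GenomicInterval],
    fragments_per_sample: dict[str, list[GenomicInterval]],
) -> tuple[np.ndarray, list[str]]:
    """Count fragments overlapping each region by >= 1 bp.

    A fragment overlapping two regions increments both. Returns the
    regions x samples matrix and the sample order.
    """
    samples = list(fragments_per_sample)
    index = IntervalIndex(reference)
    counts = np.zeros((len(reference), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for frag in fragments_per_sample[sample]:
            for ri in index.overlapping(frag):
                counts[ri, j] += 1
    return counts, samples


def scale_track(track: SignalTrack, target_fragments: int,
                observed_fragments: float | None = None) -> SignalTrack:
    """Scale a signal track to a target fragment count.

    ``observed_fragments`` defaults to the track's total signal. Values
    are multiplied by target/observed and the factor recorded on the
    returned track.
    """
    observed = track.total_signal() if observed_fragments is None else float(
        observed_fragments)
    if observed <= 0:
        raise ValueError("cannot scale a track with zero observed fragments")
    return track.scaled(target_fragments / observed)
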