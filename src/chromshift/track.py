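"""Step-function signal tracks (bedGraph semantics).

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping
intervals with a constant value each; positions not covered by any
interval have value 0. Window means are computed from a cumulative
integral so that profile extraction over thousands of anchors is O(log n)
per window edge.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from . import io as csio


class SignalTrack:
    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        scale_factor: float = 1.0,
    ):
        if not np.isfinite(scale_factor) or scale_factor <= 0:
            raise ValueError("scale_factor must be positive and finite")
        self.scale_factor = float(scale_factor)
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, vals) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            vals = np.asarray(vals, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, vals = starts[order], ends[order], vals[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite track values on {chrom}")
            self._data[chrom] = (starts, ends, vals)
            # cumulative integral of value over [0, breakpoints]
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(vals * (ends - starts))]
            )

    @classmethod
    def from_bedgraph(cls, path: str | os.PathLike) -> "SignalTrack":
        return cls(csio.read_bedgraph(path))

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        csio.write_bedgraph(self._data, path)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def total_signal(self) -> float:
        return float(sum(c[-1] for c in self._cum.values()))

    def _integral_to(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, pos) (vectorized)."""
        starts, ends, vals = self._data[chrom]
        cum = self._cum[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        # intervals 0..j-2 lie fully left of pos; interval j-1 may be partial
        j = np.searchsorted(starts, pos, side="right")
        prev = np.maximum(j - 1, 0)
        base = np.where(j > 0, cum[prev], 0.0)
        covered = np.clip(pos - starts[prev], 0, ends[prev] - starts[prev])
        partial = np.where(j > 0, vals[prev] * covered, 0.0)
        return base + partial

    def window_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean value over consecutive windows given bin edge positions.

        ``edges`` has shape (n_bins + 1,) or (n_windows, n_bins + 1).
        Positions outside the covered range (including negatives) count as 0.
        """
        edges = np.asarray(edges)
        if chrom not in self._data:
            return np.zeros(edges.shape[:-1] + (edges.shape[-1] - 1,))
        clipped = np.clip(edges, 0, None)
        flat = self._integral_to(chrom, clipped.reshape(-1)).reshape(clipped.shape)
        widths = np.diff(edges, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.diff(flat, axis=-1) / widths
        return np.where(widths > 0, means, 0.0)

    def values_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Point values (vectorized); 0 where uncovered."""
        if chrom not in self._data:
            return np.zeros(len(pos))
        starts, ends, vals = self._data[chrom]
        pos = np.asarray(pos, dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        jj = np.maximum(j, 0)
        inside = (j >= 0) & (pos < ends[jj])
        return np.where(inside, vals[jj], 0.0)

    def scaled(self, factor: float) -> "SignalTrack":
        out = SignalTrack(
            {
                c: (s.copy(), e.copy(), v * factor)
                for c, (s, e, v) in self._data.items()
            },
            scale_factor=self.scale_factor * factor,
        )
        return out

    def data(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        return self._data
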