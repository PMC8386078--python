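"""Readers and writers for the text formats the pipeline speaks.

BED-family parsing is deliberately strict: malformed lines raise with the
offending line number, and all coordinates are kept 0-based half-open
exactly as stored on disk. Tables go through pandas with a fixed float
format so that reruns are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Summit

NA_REP = "NA"
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class NarrowPeak:
    """A narrowPeak record: interval + score columns + summit offset."""

    interval: GenomicInterval
    signal: float
    pvalue: float
    qvalue: float
    summit_offset: int

    @property
    def summit(self) -> Summit:
        return Summit(
            self.interval.chrom,
            self.interval.start + self.summit_offset,
            self.interval,
        )


@dataclass(frozen=True)
class LoopRecord:
    """A BEDPE loop: two anchors plus any extra columns."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    name: str = "."
    fields: tuple = ()


def _parse_coords(chrom: str, start_s: str, end_s: str, path: str, lineno: int):
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end <= start ({start} >= {end})")
    return chrom, start, end


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6; returns intervals exactly as stored (0-based)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = _parse_coords(f[0], f[1], f[2], str(path), lineno)
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def read_narrowpeak(path: str | os.PathLike) -> list[NarrowPeak]:
    """Read ENCODE narrowPeak (BED6+4). Column 9 is -log10(q) by the
    standard; here the column is interpreted as stored by the upstream
    caller via :func:`narrowpeak_qvalue`."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(f)}"
                )
            chrom, start, end = _parse_coords(f[0], f[1], f[2], str(path), lineno)
            iv = GenomicInterval(chrom, start, end, f[5], f[3],
                                 float(f[4]) if f[4] != "." else 0.0)
            summit_offset = int(f[9])
            if summit_offset >= 0 and not (0 <= summit_offset < end - start):
                raise FormatError(f"{path}:{lineno}: summit offset outside peak")
            out.append(
                NarrowPeak(iv, float(f[6]), float(f[7]), float(f[8]), summit_offset)
            )
    return out


def narrowpeak_qvalue(peak: NarrowPeak) -> float:
    """q-value from the -log10(q) narrowPeak column."""
    if peak.qvalue < 0:
        raise FormatError("narrowPeak record lacks a q-value (column 9 < 0)")
    return float(10.0 ** (-peak.qvalue))


def read_bedpe(path: str | os.PathLike) -> list[LoopRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            c1 = _parse_coords(f[0], f[1], f[2], str(path), lineno)
            c2 = _parse_coords(f[3], f[4], f[5], str(path), lineno)
            name = f[6] if len(f) > 6 else "."
            out.append(
                LoopRecord(GenomicInterval(*c1), GenomicInterval(*c2), name,
                           tuple(f[7:]))
            )
    return out


def read_intervals(path: str | os.PathLike, format: str):
    """Dispatching reader for the three BED-family formats."""
    readers = {"BED": read_bed, "narrowPeak": read_narrowpeak, "BEDPE": read_bedpe}
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path)


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def write_bedpe(loops: Iterable[LoopRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            extra = ("\t" + "\t".join(str(x) for x in lp.fields)) if lp.fields else ""
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{lp.name}{extra}\n"
            )


def read_bedgraph(path: str | os.PathLike) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read bedGraph into per-chromosome (starts, ends, values) arrays."""
    chroms: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end = _parse_coords(f[0], f[1], f[2], str(path), lineno)
            chroms.setdefault(chrom, []).append((start, end, float(f[3])))
    out = {}
    for chrom, rows in chroms.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        vals = np.array([r[2] for r in rows])
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
        out[chrom] = (starts, ends, vals)
    return out


def write_bedgraph(
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(data):
            starts, ends, vals = data[chrom]
            for s, e, v in zip(starts, ends, vals):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a TSV with header, deterministic column order and fixed float
    rendering; NaN becomes "NA"."""
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"records missing schema columns: {missing}")
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP, float_format=FLOAT_FORMAT)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP])


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name for iv in intervals],
            "score": [iv.score for iv in intervals],
            "strand": [iv.strand for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(
            str(r.chrom), int(r.start), int(r.end),
            str(getattr(r, "strand", ".")), str(getattr(r, "name", ".")),
            float(getattr(r, "score", 0.0)),
        )
        for r in df.itertuples(index=False)
    ]
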