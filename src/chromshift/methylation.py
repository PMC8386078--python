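"""Per-CpG differential methylation, DMR merging, and methylation
meta-profiles.

Input is a table of per-CpG methylated/total counts for two conditions
(replicates pooled by summing counts upstream). The site-level test is a
two-sided Fisher exact test on the methylated/unmethylated 2x2 table,
which stays valid at low coverage; DMRs are runs of >= 3 significant
(p <= 0.01), same-direction CpGs spanning >= 50 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .stats import fisher_exact_two_sided

logger = logging.getLogger(__name__)

CPG_COLUMNS = ["chrom", "pos", "meth_ctrl", "total_ctrl", "meth_trt", "total_trt"]


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    n_cpg: int
    mean_delta: float
    direction: str  # "hyper" (treated gains methylation) or "hypo"

    def __post_init__(self) -> None:
        if len(self.interval) < 50 or self.n_cpg < 3:
            raise ValueError("DMR must span >= 50 bp and >= 3 CpGs")


def cpg_test(records: pd.DataFrame, min_cov: int = 5) -> pd.DataFrame:
    """Per-CpG methylation ratios, delta (treated - control) and Fisher p.

    CpGs with coverage below ``min_cov`` in either condition are excluded
    (logged).
    """
    df = records.copy()
    missing = [c for c in CPG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CpG table missing columns: {missing}")
    bad = (df["meth_ctrl"] > df["total_ctrl"]) | (df["meth_trt"] > df["total_trt"])
    if bad.any():
        raise ValueError("methylated count exceeds total count")
    keep = (df["total_ctrl"] >= min_cov) & (df["total_trt"] >= min_cov)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("cpg_test: %d CpGs below coverage %d excluded", n_drop, min_cov)
    df = df.loc[keep].reset_index(drop=True)
    df["ratio_ctrl"] = df["meth_ctrl"] / df["total_ctrl"]
    df["ratio_trt"] = df["meth_trt"] / df["total_trt"]
    df["delta"] = df["ratio_trt"] - df["ratio_ctrl"]
    df["p"] = fisher_exact_two_sided(
        df["meth_trt"].to_numpy(),
        (df["total_trt"] - df["meth_trt"]).to_numpy(),
        df["meth_ctrl"].to_numpy(),
        (df["total_ctrl"] - df["meth_ctrl"]).to_numpy(),
    ) if len(df) else np.zeros(0)
    return df


def call_dmrs(
    tested: pd.DataFrame,
    p_cut: float = 0.01,
    min_len: int = 50,
    min_cpg: int = 3,
    max_gap: int = 200,
) -> list[DMR]:
    """Merge significant CpGs (p <= p_cut, |delta| > 0) with consistent
    sign and successive gaps <= max_gap; emit runs meeting the minimum
    length and CpG count."""
    sig = tested.loc[(tested["p"] <= p_cut) & (tested["delta"].abs() > 0)]
    out: list[DMR] = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        sign = np.sign(delta)
        run_start = 0
        for i in range(1, len(pos) + 1):
            boundary = (
                i == len(pos)
                or pos[i] - pos[i - 1] > max_gap
                or sign[i] != sign[i - 1]
            )
            if boundary:
                n = i - run_start
                span = int(pos[i - 1] - pos[run_start] + 1)
                if n >= min_cpg and span >= min_len:
                    out.append(
                        DMR(
                            GenomicInterval(str(chrom), int(pos[run_start]),
                                            int(pos[i - 1]) + 1),
                            n,
                            float(np.mean(delta[run_start:i])),
                            "hyper" if sign[run_start] > 0 else "hypo",
                        )
                    )
                run_start = i
    return out


def meta_methylation(
    records: pd.DataFrame,
    anchors: list[tuple[str, int]],
    half_width: int,
    bins: int,
) -> pd.DataFrame:
    """Coverage-weighted mean methylation ratio per bin per condition
    around anchors. Bins without any CpG are reported as NaN (missing),
    never as 0."""
    edges = np.linspace(-half_width, half_width, bins + 1)
    meth_c = np.zeros(bins)
    tot_c = np.zeros(bins)
    meth_t = np.zeros(bins)
    tot_t = np.zeros(bins)
    by_chrom = {
        str(chrom): sub.sort_values("pos", kind="stable")
        for chrom, sub in records.groupby("chrom")
    }
    for chrom, pos in anchors:
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        p = sub["pos"].to_numpy()
        lo = np.searchsorted(p, pos - half_width, side="left")
        hi = np.searchsorted(p, pos + half_width, side="right")
        if hi <= lo:
            continue
        rel = p[lo:hi] - pos
        idx = np.clip(np.digitize(rel, edges) - 1, 0, bins - 1)
        np.add.at(meth_c, idx, sub["meth_ctrl"].to_numpy()[lo:hi])
        np.add.at(tot_c, idx, sub["total_ctrl"].to_numpy()[lo:hi])
        np.add.at(meth_t, idx, sub["meth_trt"].to_numpy()[lo:hi])
        np.add.at(tot_t, idx, sub["total_trt"].to_numpy()[lo:hi])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_c = np.where(tot_c > 0, meth_c / tot_c, np.nan)
        ratio_t = np.where(tot_t > 0, meth_t / tot_t, np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame(
        {"bin_center": centers, "ratio_ctrl": ratio_c, "ratio_trt": ratio_t,
         "coverage_ctrl": tot_c, "coverage_trt": tot_t}
    )
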