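"""Integrative analyses: promoter assignment, DAR-DEG association,
gene-set enrichment, insulator discovery, loop contact changes and TAD
boundary distances."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex, nearest_point_distance
from .io import LoopRecord
from .stats import fisher_exact_two_sided, odds_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """One TSS of a gene with its promoter window (TSS +/- promoter_half)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    promoter_half: int = 2000

    @property
    def promoter(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            max(0, self.tss - self.promoter_half),
            self.tss + self.promoter_half + 1,
            self.strand,
            self.gene_id,
        )


@dataclass(frozen=True)
class InsulatorCandidate:
    dar: GenomicInterval
    ctcf_peak: str
    gene_id: str
    tss_distance: int
    loop_support: bool

    def __post_init__(self) -> None:
        if not (2000 <= self.tss_distance <= 50_000):
            raise ValueError("insulator TSS distance outside the 2-50 kb window")


def read_gene_models(path: str, promoter_half: int = 2000) -> list[GeneModel]:
    """TSV with columns gene, chrom, tss, strand (one row per TSS)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene), str(r.chrom), int(r.tss), str(r.strand),
                  promoter_half)
        for r in df.itertuples(index=False)
    ]


def assign_promoters(
    regions: list[GenomicInterval], genes: list[GeneModel]
) -> pd.DataFrame:
    """Region-gene pairs where the region overlaps the promoter window by
    >= 1 bp; many-to-many."""
    index = IntervalIndex([g.promoter for g in genes])
    rows = []
    for ri, region in enumerate(regions):
        for gi in index.overlapping(region):
            rows.append({"region_index": ri, "gene": genes[gi].gene_id})
    return pd.DataFrame(rows, columns=["region_index", "gene"])


def dar_deg_association(
    promoter_pairs: pd.DataFrame,
    region_classes: pd.Series,
    gene_classes: pd.Series,
) -> pd.DataFrame:
    """Per-direction 2x2 Fisher tables of DAR class vs DEG class over
    promoter-assigned pairs.

    ``region_classes`` maps region_index -> {decreased, increased,
    control, unclassified}; ``gene_classes`` maps gene -> {down, up,
    none}. For each (dar_class, deg_class) direction pair the table is
    (DAR-class pair vs control-region pair) x (DEG-class gene vs
    non-DEG gene). Counts are always reported; zero cells fall back to
    the Haldane-corrected odds ratio (flagged).
    """
    pairs = promoter_pairs.copy()
    pairs["dar_class"] = pairs["region_index"].map(region_classes)
    pairs["deg_class"] = pairs["gene"].map(gene_classes).fillna("none")
    out = []
    for dar_class, deg_class in (("decreased", "down"), ("increased", "up")):
        is_dar = pairs["dar_class"] == dar_class
        is_ctrl = pairs["dar_class"] == "control"
        is_deg = pairs["deg_class"] == deg_class
        a = int((is_dar & is_deg).sum())
        b = int((is_dar & ~is_deg).sum())
        c = int((is_ctrl & is_deg).sum())
        d = int((is_ctrl & ~is_deg).sum())
        haldane = min(a, b, c, d) == 0
        out.append(
            {
                "dar_class": dar_class,
                "deg_class": deg_class,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds_ratio(a, b, c, d, haldane=haldane),
                "haldane": haldane,
                "p": float(fisher_exact_two_sided(a, b, c, d)[0]),
            }
        )
    return pd.DataFrame(out)


# -- GSEA ---------------------------------------------------------------


def gsea_es(ranked_genes: list[str], scores: np.ndarray, gene_set: set[str],
            weight: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of one set against a
    ranking (descending by score). The sign is that of the most extreme
    running-sum deviation."""
    in_set = np.array([g in gene_set for g in ranked_genes])
    if not in_set.any():
        raise ValueError("gene set does not intersect the ranking")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit = np.where(in_set, w, 0.0)
    denom_hit = hit.sum()
    if denom_hit == 0:  # all-zero scores in set with weight > 0
        hit = in_set.astype(float)
        denom_hit = hit.sum()
    n_miss = (~in_set).sum()
    p_hit = np.cumsum(hit) / denom_hit
    p_miss = np.cumsum(~in_set) / max(n_miss, 1)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def gsea(
    scores_by_gene: pd.Series,
    gene_sets: dict[str, set[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA of each set against a gene ranking by log2FC.

    The null is gene-label permutation: for each set size, random sets
    of the same size are drawn from the ranking. NES = ES / mean(|null
    ES| of the same sign); p is the fraction of same-sign null ES at
    least as extreme. Sets with no gene in the ranking are skipped with
    a warning.
    """
    rng = np.random.default_rng(seed)
    order = scores_by_gene.sort_values(ascending=False, kind="stable")
    ranked = list(order.index.astype(str))
    scores = order.to_numpy(dtype=float)
    rows = []
    for set_name, genes in gene_sets.items():
        present = {g for g in genes if g in order.index}
        if not present:
            logger.warning("gsea: set %s does not intersect ranking; skipped",
                           set_name)
            continue
        es = gsea_es(ranked, scores, present, weight)
        size = len(present)
        null_es = np.empty(n_perm)
        idx_all = np.arange(len(ranked))
        for b in range(n_perm):
            pick = rng.choice(idx_all, size=size, replace=False)
            null_set = {ranked[i] for i in pick}
            null_es[b] = gsea_es(ranked, scores, null_set, weight)
        same = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
            nes = es / np.mean(np.abs(same))
        rows.append({"set": set_name, "size": size, "es": es, "nes": nes, "p": p})
    return pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"])


def make_topk_sets(
    de_table: pd.DataFrame,
    ks: tuple[int, ...] = (100, 200, 500, 1000),
    q_cut: float = 0.05,
    prefix: str = "top",
) -> dict[str, set[str]]:
    """Top-k gene sets by |log2FC| among significant features (q < q_cut).

    Keys are f"{prefix}{k}"; sets are nested (top100 subset of top200).
    If fewer than k genes are available the full set is used (logged).
    """
    sig = de_table.loc[de_table["q"] < q_cut].copy()
    sig = sig.reindex(sig["log2fc"].abs().sort_values(ascending=False, kind="stable").index)
    genes = sig["feature"].astype(str).tolist()
    out = {}
    for k in sorted(ks):
        if k > len(genes):
            logger.info("make_topk_sets: k=%d exceeds %d available genes",
                        k, len(genes))
        out[f"{prefix}{k}"] = set(genes[:k])
    return out


# -- insulator discovery ------------------------------------------------


def discover_insulators(
    nfr_table: pd.DataFrame,
    regions: list[GenomicInterval],
    summit_pos: np.ndarray,
    ctcf_peaks: list[GenomicInterval],
    conserved_motif: np.ndarray,
    genes: list[GeneModel],
    gene_table: pd.DataFrame,
    loops: list[LoopRecord],
    min_dist: int = 2000,
    max_dist: int = 50_000,
    fc_cut: float = 2.0,
    q_cut: float = 0.05,
    promoter_half: int = 2000,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Putative insulator sites: increased DARs at conserved CTCF peaks
    that sit 2-50 kb from an upregulated gene's TSS, with optional loop
    support.

    Steps: (1) reference regions overlapping a CTCF peak flagged as
    containing a conserved CTCF motif; (2) restrict to increased DARs
    (q < q_cut, FC > fc_cut); (3) pair with upregulated genes whose TSS
    lies ``min_dist..max_dist`` from the DAR summit; (4) loop support iff
    one loop anchor overlaps the DAR and the other overlaps the gene's
    promoter window. One candidate per gene (the nearest qualifying DAR).
    Deterministic and order-independent.
    """
    if conserved_motif is None:
        raise ValueError("conserved-motif flags are required")
    conserved_motif = np.asarray(conserved_motif, dtype=bool)
    if len(conserved_motif) != len(ctcf_peaks):
        raise ValueError("conserved flags must align with CTCF peaks")
    ctcf_idx = IntervalIndex([p for p, c in zip(ctcf_peaks, conserved_motif) if c])
    ctcf_names = [p.name for p, c in zip(ctcf_peaks, conserved_motif) if c]

    step1 = [
        i for i, r in enumerate(regions) if ctcf_idx.overlapping(r)
    ]
    lfc = nfr_table["log2fc"].to_numpy(dtype=float)
    q = nfr_table["q"].to_numpy(dtype=float)
    lcut = np.log2(fc_cut)
    step2 = [i for i in step1 if q[i] < q_cut and lfc[i] > lcut]

    up_genes = gene_table.loc[
        (gene_table["q"] < q_cut) & (gene_table["log2fc"] > lcut), "feature"
    ].astype(str)
    up_set = set(up_genes)

    loop_idx1 = IntervalIndex([lp.anchor1 for lp in loops])
    loop_idx2 = IntervalIndex([lp.anchor2 for lp in loops])

    rows = []
    for g in sorted(
        (g for g in genes if g.gene_id in up_set),
        key=lambda g: (g.gene_id, g.chrom, g.tss),
    ):
        best = None
        for i in step2:
            r = regions[i]
            if r.chrom != g.chrom:
                continue
            dist = abs(int(summit_pos[i]) - g.tss)
            if not (min_dist <= dist <= max_dist):
                continue
            if best is None or dist < best[0]:
                best = (dist, i)
        if best is None:
            continue
        dist, i = best
        dar = regions[i]
        promoter = GenomicInterval(
            g.chrom, max(0, g.tss - promoter_half), g.tss + promoter_half + 1
        )
        support = _loop_supports(dar, promoter, loops, loop_idx1, loop_idx2)
        peak_ids = [
            ctcf_names[j] for j in ctcf_idx.overlapping(dar)
        ]
        rows.append(
            {
                "gene": g.gene_id,
                "chrom": g.chrom,
                "dar_start": dar.start,
                "dar_end": dar.end,
                "dar_index": i,
                "ctcf_peak": peak_ids[0] if peak_ids else ".",
                "tss_distance": dist,
                "loop_support": support,
            }
        )
    counts = {
        "step1_ctcf_overlap": len(step1),
        "step2_increased": len(step2),
        "candidates": len(rows),
        "loop_supported": int(sum(r["loop_support"] for r in rows)),
    }
    df = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "dar_start", "dar_end", "dar_index",
                 "ctcf_peak", "tss_distance", "loop_support"],
    )
    return df, counts


def _loop_supports(dar, promoter, loops, idx1, idx2) -> bool:
    for li in idx1.overlapping(dar):
        if loops[li].anchor2.overlaps(promoter):
            return True
    for li in idx2.overlapping(dar):
        if loops[li].anchor1.overlaps(promoter):
            return True
    return False


# -- loops and TADs -----------------------------------------------------


def loop_contact_change(
    loops: list[LoopRecord],
    contacts_ctrl: np.ndarray,
    contacts_trt: np.ndarray,
    regions: list[GenomicInterval],
    region_classes: pd.Series | np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-loop log2 contact change grouped by overlapped region class.

    A loop joins a class if either anchor overlaps a region of that
    class; when several classes apply the precedence is decreased >
    increased > control (reported in the group column as-is). Loops
    touching only unclassified regions are excluded. Returns (per-loop
    table, pairwise two-sided rank-sum tests between groups).
    """
    contacts_ctrl = np.asarray(contacts_ctrl, dtype=float)
    contacts_trt = np.asarray(contacts_trt, dtype=float)
    if np.any(contacts_ctrl <= 0) or np.any(contacts_trt <= 0):
        raise ValueError("contacts must be > 0 for log2 fold change")
    classes = np.asarray(region_classes, dtype=object)
    index = IntervalIndex(regions)
    rows = []
    for li, lp in enumerate(loops):
        touched = {
            classes[ri]
            for anchor in (lp.anchor1, lp.anchor2)
            for ri in index.overlapping(anchor)
        }
        group = None
        for cls in ("decreased", "increased", "control"):
            if cls in touched:
                group = cls
                break
        if group is None:
            continue
        rows.append(
            {
                "loop_index": li,
                "group": group,
                "log2fc": float(np.log2(contacts_trt[li] / contacts_ctrl[li])),
            }
        )
    per_loop = pd.DataFrame(rows, columns=["loop_index", "group", "log2fc"])
    tests = []
    groups = ["decreased", "control", "increased"]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x = per_loop.loc[per_loop["group"] == groups[i], "log2fc"]
            y = per_loop.loc[per_loop["group"] == groups[j], "log2fc"]
            if len(x) == 0 or len(y) == 0:
                continue
            stat = stats.mannwhitneyu(x, y, alternative="two-sided")
            tests.append(
                {"group1": groups[i], "group2": groups[j],
                 "n1": len(x), "n2": len(y),
                 "median1": float(x.median()), "median2": float(y.median()),
                 "p": float(stat.pvalue)}
            )
    return per_loop, pd.DataFrame(tests)


def tad_distance(
    summit_pos_by_region: list[tuple[str, int]],
    region_classes: list[str] | np.ndarray,
    boundaries: list[GenomicInterval],
) -> pd.DataFrame:
    """Distance from each region's summit to the nearest TAD boundary
    midpoint, with per-class quantile summaries available downstream.
    Regions on chromosomes without boundaries are excluded (logged)."""
    mids: dict[str, list[int]] = {}
    for b in boundaries:
        mids.setdefault(b.chrom, []).append(b.center)
    mids_arr = {c: np.array(sorted(v)) for c, v in mids.items()}
    rows = []
    n_excluded = 0
    for (chrom, pos), cls in zip(summit_pos_by_region, region_classes):
        d = nearest_point_distance(chrom, pos, mids_arr)
        if np.isnan(d):
            n_excluded += 1
            continue
        rows.append({"chrom": chrom, "pos": pos, "class": cls, "distance": d})
    if n_excluded:
        logger.info("tad_distance: %d regions on chromosomes without "
                    "boundaries excluded", n_excluded)
    return pd.DataFrame(rows, columns=["chrom", "pos", "class", "distance"])
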