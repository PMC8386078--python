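"""Multi-omics TF co-regulator discovery.

A TF is called a co-regulatory partner when its target-gene set is
significantly enriched among deregulated genes at the RNA and/or protein
layer (hypergeometric upper tail, BH-corrected per layer x direction)
AND the TF itself is detected as a quantified protein. Partners whose
own mRNA/protein/phospho change is significant are "evident"; partners
whose own levels do not move are "hidden".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .stats import bh_adjust, fisher_exact_two_sided, odds_ratio
from .motifs import regions_with_hit

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["rna_up", "rna_down", "protein_up", "protein_down"]


def de_gene_sets(
    table: pd.DataFrame, q_cut: float = 0.05
) -> tuple[set[str], set[str]]:
    """(up, down) significant gene sets from a DE table."""
    sig = table.loc[table["q"] < q_cut]
    up = set(sig.loc[sig["log2fc"] > 0, "feature"].astype(str))
    down = set(sig.loc[sig["log2fc"] < 0, "feature"].astype(str))
    return up, down


def target_enrichment(
    tf_targets: dict[str, set[str]],
    de_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric target-set enrichment per TF and DE set.

    ``de_sets`` keys become columns (e.g. rna_up). p = P(overlap >=
    observed) over the gene universe; BH is applied across TFs within
    each column. Returns a table with p_<col> and fdr_<col> columns.
    """
    for name, s in de_sets.items():
        if not s <= universe:
            raise ValueError(f"DE set {name} not contained in universe")
    rows = {"tf": list(tf_targets)}
    N = len(universe)
    for col, de in de_sets.items():
        pvals = []
        for tf, targets in tf_targets.items():
            t = targets & universe
            if not targets <= universe:
                raise ValueError(f"targets of {tf} not contained in universe")
            k = len(t & de)
            pvals.append(float(stats.hypergeom.sf(k - 1, N, len(de), len(t))))
        rows[f"p_{col}"] = pvals
        rows[f"fdr_{col}"] = bh_adjust(np.array(pvals))
    return pd.DataFrame(rows)


def ms_filter(
    tfs: list[str],
    protein_table: pd.DataFrame,
    id_map: dict[str, str] | None = None,
) -> pd.Series:
    """ms_detected flag: the TF appears as a quantified protein row.

    ``id_map`` resolves TF id -> protein row id for alias mismatches;
    unmapped aliases count as not detected (warned)."""
    detected = set(protein_table["feature"].astype(str))
    flags = {}
    for tf in tfs:
        name = (id_map or {}).get(tf, tf)
        flags[tf] = name in detected
        if id_map is not None and tf in id_map and name not in detected:
            logger.warning("ms_filter: mapped id %s -> %s not in protein table",
                           tf, name)
    return pd.Series(flags, name="ms_detected")


def own_change(
    tfs: list[str],
    rna: pd.DataFrame,
    protein: pd.DataFrame,
    phospho: pd.DataFrame,
    phospho_gene_col: str = "gene",
) -> pd.DataFrame:
    """Per-TF own-change FDRs and log2FCs in the three layers.

    mRNA and protein are row lookups; the phospho layer is summarized as
    the minimum FDR across the TF's phosphopeptides. A TF absent from a
    layer gets a missing value (NaN), not 1.0.
    """
    def lookup(table: pd.DataFrame, tf: str) -> tuple[float, float]:
        sub = table.loc[table["feature"].astype(str) == tf]
        if len(sub) == 0:
            return np.nan, np.nan
        return float(sub["q"].iloc[0]), float(sub["log2fc"].iloc[0])

    rows = []
    for tf in tfs:
        rna_q, rna_fc = lookup(rna, tf)
        prot_q, prot_fc = lookup(protein, tf)
        pep = phospho.loc[phospho[phospho_gene_col].astype(str) == tf]
        if len(pep) == 0:
            ph_q, ph_fc = np.nan, np.nan
        else:
            i = pep["q"].idxmin()
            ph_q, ph_fc = float(pep.loc[i, "q"]), float(pep.loc[i, "log2fc"])
        rows.append(
            {"tf": tf, "rna_fdr": rna_q, "rna_log2fc": rna_fc,
             "protein_fdr": prot_q, "protein_log2fc": prot_fc,
             "phospho_fdr": ph_q, "phospho_log2fc": ph_fc}
        )
    return pd.DataFrame(rows)


def dar_motif_or(
    hits: pd.DataFrame,
    decreased: list[GenomicInterval],
    increased: list[GenomicInterval],
    control: list[GenomicInterval],
) -> dict[str, float]:
    """log2 odds ratios of motif-bearing regions: each DAR class vs
    control, Haldane-corrected when a cell is zero."""
    out = {}
    c = int(regions_with_hit(control, hits).sum())
    d = len(control) - c
    for name, cls in (("decreased", decreased), ("increased", increased)):
        a = int(regions_with_hit(cls, hits).sum())
        b = len(cls) - a
        haldane = min(a, b, c, d) == 0
        out[f"log2_or_{name}"] = float(
            np.log2(odds_ratio(a, b, c, d, haldane=haldane))
        )
        out[f"haldane_{name}"] = haldane
    return out


def classify_partners(
    report: pd.DataFrame,
    enr_fdr: float = 0.05,
    own_fdr: float = 0.05,
) -> pd.DataFrame:
    """Partner classification.

    partner iff (any target-enrichment FDR < enr_fdr) and ms_detected;
    evident iff additionally any own-change FDR < own_fdr; hidden iff
    partner without a significant own change. Missing own-change values
    do not count as significant.
    """
    out = report.copy()
    enr_cols = [f"fdr_{c}" for c in ENRICH_COLUMNS if f"fdr_{c}" in out.columns]
    own_cols = [c for c in ("rna_fdr", "protein_fdr", "phospho_fdr")
                if c in out.columns]
    enriched = (out[enr_cols] < enr_fdr).any(axis=1)
    own_sig = (out[own_cols] < own_fdr).any(axis=1) if own_cols else False
    partner = enriched & out["ms_detected"].astype(bool)
    cls = np.where(partner, np.where(own_sig, "evident", "hidden"), "none")
    out["class"] = cls
    return out


def essentiality_enrichment(
    partners: set[str], essential: set[str], tf_universe: set[str]
) -> dict[str, float]:
    """Two-sided Fisher test of partner x essential over the TF universe."""
    if not partners <= tf_universe or not essential <= tf_universe:
        raise ValueError("partner and essential sets must lie in the universe")
    a = len(partners & essential)
    b = len(partners - essential)
    c = len(essential - partners)
    d = len(tf_universe - partners - essential)
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": odds_ratio(a, b, c, d, haldane=min(a, b, c, d) == 0),
        "p": float(fisher_exact_two_sided(a, b, c, d)[0]),
    }
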