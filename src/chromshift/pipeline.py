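"""Stage orchestration: chains simulation and every analysis stage over
a directory of TSV/BED-family files, with a provenance sidecar per stage.

Stages (in dependency order): simulate, nfr, dars, motifs, profiles,
methylation, integrate, partners. Rerunning a stage with the same config
and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .difftest import classify_features, moderated_test, tmm_factors
from .integration import (assign_promoters, dar_deg_association,
                          discover_insulators, gsea, loop_contact_change,
                          make_topk_sets, read_gene_models, tad_distance)
from .intervals import GenomicInterval, Summit
from .io import (frame_to_intervals, intervals_to_frame, read_bed,
                 read_bedpe, read_narrowpeak, read_table, write_table)
from .methylation import call_dmrs, cpg_test, meta_methylation
from .motifs import (enrichment_volcano, nearest_motif_distance,
                     orient_summits, read_pwms, scan_pwm, tandem_sites)
from .coregulators import (classify_partners, dar_motif_or, de_gene_sets,
                           essentiality_enrichment, ms_filter, own_change,
                           target_enrichment)
from .peaks import build_reference_nfrs, refine_summits
from .profiles import (classify_shape, extract_matrix, footprint,
                       kmeans_profiles, orientation_bias)
from .simulate import SimConfig, simulate_study
from .track import SignalTrack

logger = logging.getLogger(__name__)

STAGES = ("simulate", "nfr", "dars", "motifs", "profiles", "methylation",
          "integrate", "partners")


class MissingUpstreamError(RuntimeError):
    pass


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(
            f"missing {path.name}; run the '{stage}' stage first")
    return path


class Pipeline:
    def __init__(self, config: RunConfig, sim_config: SimConfig | None = None):
        self.config = config
        self.sim_config = sim_config or SimConfig(seed=config.seed)
        self.outdir = Path(config.outdir)
        self.inputs = self.outdir / "inputs"

    # -- plumbing ------------------------------------------------------

    def _provenance(self, stage: str) -> None:
        payload = {
            "stage": stage,
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "version": __version__,
        }
        with open(self.outdir / f"{stage}.provenance.json", "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    def run(self, stages: set[str] | None = None) -> None:
        wanted = set(stages or {"all"})
        if "all" in wanted:
            wanted = set(STAGES)
        unknown = wanted - set(STAGES) - {"all"}
        if unknown:
            raise ValueError(
                f"unknown stages {sorted(unknown)}; valid: {list(STAGES)} or 'all'")
        for stage in STAGES:
            if stage in wanted:
                logger.info("running stage %s", stage)
                getattr(self, f"stage_{stage}")()
                self._provenance(stage)

    # -- stages --------------------------------------------------------

    def stage_simulate(self) -> None:
        study = simulate_study(self.sim_config)
        study.write(self.inputs)

    def stage_nfr(self) -> None:
        group_peaks = {}
        for grp in ("ctrl", "trt"):
            group_peaks[grp] = read_narrowpeak(
                _need(self.inputs / f"peaks_{grp}.narrowPeak", "simulate"))
        reference = build_reference_nfrs(
            group_peaks, self.config.stringent_q, self.config.lenient_q)
        summits = []
        for path in sorted(self.inputs.glob("summits_*.bed")):
            summits += [Summit(iv.chrom, iv.start) for iv in read_bed(path)]
        kept, log = refine_summits(reference, summits,
                                   self.config.min_summit_separation)
        ref_df = intervals_to_frame(reference)
        ref_df["name"] = [f"nfr_{i:05d}" for i in range(len(reference))]
        write_table(ref_df, self.outdir / "reference_nfrs.tsv")
        write_table(
            pd.DataFrame(
                {
                    "region": [f"nfr_{reference.index(region):05d}"
                               for region, _ in kept],
                    "chrom": [s.chrom for _, s in kept],
                    "pos": [s.pos for _, s in kept],
                }
            ),
            self.outdir / "refined_summits.tsv",
        )
        with open(self.outdir / "nfr.log.json", "w") as fh:
            json.dump(log, fh, sort_keys=True)

    def stage_dars(self) -> None:
        counts = read_table(_need(self.inputs / "counts.tsv", "simulate"))
        design = read_table(self.inputs / "design.tsv")
        samples = design["sample"].tolist()
        mat = counts[samples].to_numpy()
        factors = tmm_factors(mat)
        table = moderated_test(
            mat, factors, design["group"].to_numpy(), "ctrl", "trt",
            feature_ids=counts["region"].astype(str).tolist(),
        )
        table = classify_features(
            table, self.config.fc_cut, self.config.q_cut,
            self.config.ctrl_p, self.config.ctrl_fc,
        )
        write_table(table, self.outdir / "dar_table.tsv")
        write_table(
            pd.DataFrame({"sample": samples, "tmm_factor": factors}),
            self.outdir / "tmm_factors.tsv",
        )

    # helpers shared by downstream stages -------------------------------

    def _load_regions(self) -> tuple[list[GenomicInterval], pd.DataFrame]:
        ref = read_table(_need(self.outdir / "reference_nfrs.tsv", "nfr"))
        table = read_table(_need(self.outdir / "dar_table.tsv", "dars"))
        return frame_to_intervals(ref), table

    def _load_summits(self) -> pd.DataFrame:
        return read_table(_need(self.outdir / "refined_summits.tsv", "nfr"))

    def _genome(self) -> dict[str, str]:
        from pyfaidx import Fasta

        fa = Fasta(str(_need(self.inputs / "genome.fa", "simulate")))
        return {name: str(fa[name][:]) for name in fa.keys()}

    def _class_regions(self, regions, table) -> dict[str, list[GenomicInterval]]:
        cls = table["class"].to_numpy()
        return {
            c: [iv for iv, k in zip(regions, cls) if k == c]
            for c in ("decreased", "increased", "control")
        }

    def stage_motifs(self) -> None:
        genome = self._genome()
        pwms = read_pwms(str(_need(self.inputs / "motifs.pwm", "simulate")),
                         background=None, pseudo=self.config.motif_pseudo)
        regions, table = self._load_regions()
        summits_df = self._load_summits()
        name_to_idx = {iv.name: i for i, iv in enumerate(regions)}
        hits_by_motif = {}
        for pwm in pwms:
            hits = scan_pwm(genome, pwm, self.config.motif_thresh_p)
            hits_by_motif[pwm.motif_id] = hits
            write_table(hits, self.outdir / f"hits_{pwm.motif_id}.tsv")
        ctcf_hits = hits_by_motif["CTCF"]
        summit_objs = [Summit(r.chrom, int(r.pos))
                       for r in summits_df.itertuples(index=False)]
        dist = nearest_motif_distance(summit_objs, ctcf_hits)
        dist["region"] = summits_df["region"].to_numpy()[
            dist["summit_index"].to_numpy()]
        dist["class"] = dist["region"].map(
            dict(zip(table["feature"], table["class"])))
        write_table(dist, self.outdir / "ctcf_distance.tsv")
        orient = orient_summits(summit_objs, ctcf_hits)
        orient["region"] = summits_df["region"].to_numpy()[
            orient["summit_index"].to_numpy()]
        write_table(orient, self.outdir / "summit_orientation.tsv")
        by_class = self._class_regions(regions, table)
        for cls in ("decreased", "increased"):
            vol = enrichment_volcano(by_class[cls], by_class["control"],
                                     hits_by_motif)
            write_table(vol, self.outdir / f"volcano_{cls}.tsv")
        tandems = tandem_sites(ctcf_hits, self.config.tandem_max_gap)
        write_table(intervals_to_frame(tandems), self.outdir / "tandem_cts.tsv")

    def stage_profiles(self) -> None:
        cutrun = SignalTrack.from_bedgraph(
            _need(self.inputs / "cutrun.bedGraph", "simulate"))
        insertion = SignalTrack.from_bedgraph(
            self.inputs / "insertion.bedGraph")
        regions, table = self._load_regions()
        summits_df = self._load_summits()
        orient = read_table(_need(self.outdir / "summit_orientation.tsv",
                                  "motifs"))
        classes = dict(zip(table["feature"], table["class"]))
        rows = []
        for cls in ("decreased", "increased", "control"):
            sel = summits_df.loc[summits_df["region"].map(classes) == cls]
            anchors = list(zip(sel["chrom"], sel["pos"].astype(int)))
            if not anchors:
                continue
            mat = extract_matrix(cutrun, anchors,
                                 self.config.cluster_half_width,
                                 self.config.heatmap_bin)
            shape = classify_shape(mat.mean_profile())
            # oriented version using nearest-motif strands
            omap = dict(zip(orient["region"],
                            orient["flip"].astype(bool)))
            flips = np.array([omap.get(r, False)
                              for r in sel["region"]])
            omat = extract_matrix(cutrun, anchors,
                                  self.config.cluster_half_width,
                                  self.config.heatmap_bin, oriented=True,
                                  flip=flips)
            oshape = classify_shape(omat.mean_profile())
            bias, bias_p, _ = orientation_bias(omat)
            n_usable = int((mat.matrix.max(axis=1) > 0).sum())
            k = min(self.config.kmeans_k, n_usable)
            if k >= 1:
                labels, _ = kmeans_profiles(
                    mat, k, seed=self.config.seed,
                    n_init=self.config.kmeans_n_init)
                n_clusters = int(labels.max() + 1)
            else:
                n_clusters = 0
            rows.append({"class": cls, "n": len(anchors),
                         "shape_unoriented": shape, "shape_oriented": oshape,
                         "upstream_bias": bias, "bias_sign_p": bias_p,
                         "n_clusters": n_clusters})
        write_table(pd.DataFrame(rows), self.outdir / "profile_shapes.tsv")
        # footprint over CTCF hits inside decreased regions
        hits = read_table(_need(self.outdir / "hits_CTCF.tsv", "motifs"))
        dec = [iv for iv, k in zip(regions, table["class"]) if k == "decreased"]
        from .motifs import _centers_in, _hits_by_chrom  # noqa: internal reuse

        by_chrom = _hits_by_chrom(hits)
        keep_rows = []
        for r in dec:
            sub = by_chrom.get(r.chrom)
            if sub is None:
                continue
            centers = _centers_in(sub, r)
            keep_rows.append(sub.loc[sub["center"].isin(centers)])
        dec_hits = (pd.concat(keep_rows, ignore_index=True)
                    if keep_rows else hits.iloc[0:0])
        prof, ratio = footprint(insertion, dec_hits, motif_width=19,
                                half_width=self.config.footprint_half_width)
        write_table(
            pd.DataFrame({"offset": np.arange(-self.config.footprint_half_width,
                                              self.config.footprint_half_width + 1),
                          "insertions": prof}),
            self.outdir / "footprint_ctcf.tsv",
        )
        with open(self.outdir / "footprint_ratio.json", "w") as fh:
            json.dump({"ctcf_decreased": ratio}, fh, sort_keys=True)

    def stage_methylation(self) -> None:
        cpg = read_table(_need(self.inputs / "cpg.tsv", "simulate"))
        tested = cpg_test(cpg, self.config.meth_min_cov)
        write_table(tested, self.outdir / "cpg_tested.tsv")
        dmrs = call_dmrs(tested, self.config.dmr_p, self.config.dmr_min_len,
                         self.config.dmr_min_cpg, self.config.dmr_max_gap)
        write_table(
            pd.DataFrame(
                [{"chrom": d.interval.chrom, "start": d.interval.start,
                  "end": d.interval.end, "n_cpg": d.n_cpg,
                  "mean_delta": d.mean_delta, "direction": d.direction}
                 for d in dmrs],
                columns=["chrom", "start", "end", "n_cpg", "mean_delta",
                         "direction"],
            ),
            self.outdir / "dmrs.tsv",
        )
        summits_df = self._load_summits()
        anchors = list(zip(summits_df["chrom"], summits_df["pos"].astype(int)))
        meta = meta_methylation(cpg, anchors, 1000, 20)
        write_table(meta, self.outdir / "meta_methylation.tsv")

    def stage_integrate(self) -> None:
        regions, table = self._load_regions()
        genes = read_gene_models(str(_need(self.inputs / "genes.tsv",
                                           "simulate")),
                                 self.config.promoter_half)
        rna = read_table(self.inputs / "rna_de.tsv")
        pairs = assign_promoters(regions, genes)
        write_table(pairs, self.outdir / "promoter_pairs.tsv")
        gene_cls = pd.Series(
            np.where(
                (rna["q"] < self.config.q_cut)
                & (rna["log2fc"] > np.log2(self.config.fc_cut)), "up",
                np.where(
                    (rna["q"] < self.config.q_cut)
                    & (rna["log2fc"] < -np.log2(self.config.fc_cut)), "down",
                    "none"),
            ),
            index=rna["feature"].astype(str),
        )
        assoc = dar_deg_association(pairs, table["class"], gene_cls)
        write_table(assoc, self.outdir / "dar_deg_association.tsv")
        # GSEA of top-k DAR-associated gene sets against the RNA ranking
        gene_sets = {}
        for cls in ("decreased", "increased"):
            cls_regions = set(table.index[table["class"] == cls])
            linked = pairs.loc[pairs["region_index"].isin(cls_regions), "gene"]
            genes_linked = rna.loc[rna["feature"].isin(set(linked))]
            gene_sets.update(
                make_topk_sets(genes_linked, q_cut=self.config.q_cut,
                               prefix=f"{cls}_top"))
        gene_sets = {k: v for k, v in gene_sets.items() if v}
        ranking = rna.set_index("feature")["log2fc"]
        gsea_table = gsea(ranking, gene_sets, weight=1.0,
                          n_perm=self.config.gsea_permutations,
                          seed=self.config.seed)
        write_table(gsea_table, self.outdir / "gsea.tsv")
        # insulators
        summits_df = self._load_summits()
        summit_map = dict(zip(summits_df["region"],
                              summits_df["pos"].astype(int)))
        summit_pos = np.array([
            summit_map.get(iv.name, iv.center) for iv in regions
        ])
        ctcf = read_table(self.inputs / "ctcf_peaks.tsv")
        ctcf_ivs = frame_to_intervals(ctcf.drop(columns=["conserved"]))
        if "conserved" not in ctcf.columns:
            raise ValueError("CTCF peak table lacks the conserved flag column")
        cands, counts = discover_insulators(
            table, regions, summit_pos, ctcf_ivs,
            ctcf["conserved"].to_numpy(dtype=bool), genes, rna,
            read_bedpe(self.inputs / "loops.bedpe"),
            self.config.insulator_min_dist, self.config.insulator_max_dist,
            self.config.fc_cut, self.config.q_cut, self.config.promoter_half,
        )
        write_table(cands, self.outdir / "insulator_candidates.tsv")
        with open(self.outdir / "insulator_counts.json", "w") as fh:
            json.dump(counts, fh, sort_keys=True)
        # loops and TADs
        loops = read_bedpe(self.inputs / "loops.bedpe")
        contacts = read_table(self.inputs / "loop_contacts.tsv")
        per_loop, tests = loop_contact_change(
            loops, contacts["contact_ctrl"].to_numpy(),
            contacts["contact_trt"].to_numpy(), regions,
            table["class"].to_numpy(),
        )
        write_table(per_loop, self.outdir / "loop_groups.tsv")
        write_table(tests, self.outdir / "loop_tests.tsv")
        boundaries = read_bed(self.inputs / "tad_boundaries.bed")
        summit_pairs = [(iv.chrom, int(p))
                        for iv, p in zip(regions, summit_pos)]
        tad = tad_distance(summit_pairs, table["class"].tolist(), boundaries)
        write_table(tad, self.outdir / "tad_distance.tsv")

    def stage_partners(self) -> None:
        regions, table = self._load_regions()
        rna = read_table(self.inputs / "rna_de.tsv")
        protein = read_table(self.inputs / "protein_de.tsv")
        phospho = read_table(self.inputs / "phospho_de.tsv")
        targets_df = read_table(_need(self.inputs / "tf_targets.tsv",
                                      "simulate"))
        tf_targets = {
            str(tf): set(sub["gene"].astype(str))
            for tf, sub in targets_df.groupby("tf")
        }
        universe = set(rna["feature"].astype(str))
        rna_up, rna_down = de_gene_sets(rna, self.config.q_cut)
        prot_up, prot_down = de_gene_sets(protein, self.config.q_cut)
        enr = target_enrichment(
            tf_targets,
            {"rna_up": rna_up, "rna_down": rna_down,
             "protein_up": prot_up & universe, "protein_down": prot_down & universe},
            universe,
        )
        tfs = list(tf_targets)
        flags = ms_filter(tfs, protein)
        own = own_change(tfs, rna, protein, phospho)
        report = enr.merge(own, on="tf")
        report["ms_detected"] = report["tf"].map(flags)
        report = classify_partners(report, self.config.partner_enr_fdr,
                                   self.config.partner_own_fdr)
        by_class = self._class_regions(regions, table)
        partner_hits = read_table(_need(self.outdir / "hits_PARTNER.tsv",
                                        "motifs"))
        ors = dar_motif_or(partner_hits, by_class["decreased"],
                           by_class["increased"], by_class["control"])
        for key, val in ors.items():
            report[f"partner_motif_{key}"] = val
        ess = read_table(self.inputs / "essential.tsv")
        essential = set(ess.loc[ess["score"] < 0.01, "gene"].astype(str))
        partners = set(report.loc[report["class"] != "none", "tf"])
        fisher = essentiality_enrichment(partners, essential & set(tfs),
                                         set(tfs))
        best = report[[c for c in report.columns
                       if c.startswith("fdr_")]].min(axis=1)
        report = report.iloc[np.argsort(best.values, kind="stable")]
        report = report.reset_index(drop=True)
        write_table(report, self.outdir / "partner_report.tsv")
        with open(self.outdir / "essentiality.json", "w") as fh:
            json.dump(fisher, fh, sort_keys=True, default=float)


def run_pipeline(config: RunConfig, stages: set[str] | None = None,
                 sim_config: SimConfig | None = None) -> None:
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    Pipeline(config, sim_config).run(stages)
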