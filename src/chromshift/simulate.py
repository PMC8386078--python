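"""Synthetic acute-TF-depletion study with planted ground truth.

The generator emits a miniature genome plus every input the analysis
stages consume — replicate ATAC peak calls and counts, occupancy and
Tn5-insertion tracks, RNA/protein/phosphopeptide differential tables,
TF target sets, an essential-gene list, loops with per-condition
contacts, TAD boundaries and CpG methylation counts — all tied to a
Truth table that downstream stages must recover.

Planted structure (defaults):

* decreased regions carry a CTCF motif at the summit, a second CTCF
  site ~200 bp away, a partner-TF motif ~40 bp from the CTCF site, and
  4-fold accessibility loss upon depletion;
* increased regions carry a CTCF motif ~100 bp from the summit and
  4-fold gain; a configurable fraction carries a ~33 bp tandem CTCF
  pair (2xCTS);
* occupancy bumps sit upstream of the CTCF motif (strand-aware), so
  unoriented averages over decreased sites show a double summit that
  resolves to a single biased summit after motif re-orientation;
* a small set of insulator units plants an increased DAR with a
  conserved CTCF site 2-50 kb from an upregulated gene inside a loop;
* partner TFs shift their target genes at the RNA and/or protein
  layer; "hidden" partners keep their own levels flat;
* loops anchored at decreased regions lose more contact than control
  loops; methylation is flat everywhere except a few planted DMRs.

Counts are negative binomial, omics effect estimates normal with
feature-level standard errors, methylation beta-binomial. Everything is
driven by one integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm

from .intervals import GenomicInterval, Summit
from .stats import bh_adjust
from .io import (LoopRecord, NarrowPeak, intervals_to_frame, write_bed,
                 write_bedpe, write_fasta, write_table)
from .motifs import PWM, write_pwms
from .track import SignalTrack

_BASES = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}

CTCF_CONSENSUS = "TGGCCACCAGGGGGCGCTA"
PARTNER_CONSENSUS = "GACCGGAAGT"
DECOY_CONSENSUS = "TGATTCAATC"


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 4
    chrom_len: int = 2_000_000
    base_comp: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    # regions
    n_decreased: int = 350
    n_increased: int = 350
    n_control: int = 350
    n_null: int = 250
    n_close_pairs: int = 12
    region_width: int = 500
    planted_log2fc: float = 2.0
    # ATAC counts
    n_rep_per_group: int = 3
    dispersion: float = 0.03
    mean_count: float = 300.0
    depth_sd: float = 0.1
    summit_jitter: int = 20
    # motif geometry
    tandem_spacing: int = 33
    wide_spacing: int = 200
    inc_motif_offset: int = 100
    partner_offset: int = 40
    tandem_frac_increased: float = 0.154
    tandem_frac_control: float = 0.024
    tandem_frac_decreased: float = 0.0138
    ctrl_motif_frac: float = 0.25
    # occupancy / insertion tracks
    occupancy_offset: int = 150
    occupancy_sigma: float = 50.0
    occupancy_amp: float = 40.0
    inc_occupancy_amp: float = 100.0
    insertion_base: float = 50.0
    protection_depth: float = 0.3
    flank_amp: float = 1.0
    # genes / omics
    n_genes: int = 800
    n_tfs: int = 60
    n_partners: int = 8
    targets_per_tf: int = 30
    omics_se: float = 0.25
    dar_gene_frac: float = 0.3
    dar_gene_effect: float = 1.8
    target_effect: float = 1.5
    insulator_effect: float = 2.0
    n_insulators: int = 12
    insulator_margin: int = 55_000   # isolation on both sides of a unit
    insulator_min_gene_dist: int = 7000
    insulator_max_gene_dist: int = 40_000
    # loops / TADs
    loops_per_class: int = 150
    loop_contact_mean: float = 100.0
    loop_loss_decreased: float = -1.5
    loop_loss_control: float = -0.5
    loop_loss_increased: float = -0.2
    loop_loss_sd: float = 0.2
    boundary_frac: float = 0.3
    # methylation
    cpg_spacing: int = 150
    meth_coverage: float = 30.0
    meth_mean: float = 0.7
    meth_precision: float = 200.0
    n_dmrs: int = 20
    dmr_n_cpg: int = 5
    dmr_cpg_gap: int = 30
    dmr_delta: float = 0.4

    def __post_init__(self) -> None:
        if self.chrom_len < 100_000:
            raise ValueError("chrom_len must be >= 100 kb")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_rep_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.n_tfs < self.n_partners:
            raise ValueError("n_tfs must cover the planted partners")


@dataclass
class Truth:
    """Planted ground truth written alongside the simulated inputs."""

    regions: pd.DataFrame          # per reference region: class, summit, motifs
    motif_placements: pd.DataFrame
    genes: pd.DataFrame            # gene, tss, planted effects, role
    partners: pd.DataFrame         # tf, kind (evident/hidden), layers
    insulators: pd.DataFrame
    loops: pd.DataFrame
    dmrs: pd.DataFrame


@dataclass
class SimulatedStudy:
    config: SimConfig
    truth: Truth
    genome: dict[str, str]
    pwms: list[PWM]
    regions: list[GenomicInterval]
    counts: np.ndarray
    samples: list[str]
    groups: np.ndarray
    group_peaks: dict[str, list[NarrowPeak]]
    replicate_summits: dict[str, list[Summit]]
    cutrun: SignalTrack
    insertion: SignalTrack
    ctcf_peaks: list[GenomicInterval]
    ctcf_conserved: np.ndarray
    gene_models: pd.DataFrame
    rna: pd.DataFrame
    protein: pd.DataFrame
    phospho: pd.DataFrame
    tf_targets: dict[str, set[str]]
    essential: pd.DataFrame
    loops: list[LoopRecord]
    loop_contacts: pd.DataFrame
    tad_boundaries: list[GenomicInterval]
    cpg_table: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write every input file the pipeline stages read, plus truth."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_pwms(self.pwms, out / "motifs.pwm")
        write_bed(self.regions, out / "regions.bed")
        counts = pd.DataFrame(self.counts, columns=self.samples)
        counts.insert(0, "region", [iv.name for iv in self.regions])
        write_table(counts, out / "counts.tsv")
        write_table(
            pd.DataFrame({"sample": self.samples, "group": self.groups}),
            out / "design.tsv",
        )
        for grp, peaks in self.group_peaks.items():
            with open(out / f"peaks_{grp}.narrowPeak", "w") as fh:
                for p in peaks:
                    iv = p.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                        f"{iv.score:g}\t{iv.strand}\t{p.signal:g}\t"
                        f"{p.pvalue:g}\t{p.qvalue:g}\t{p.summit_offset}\n"
                    )
        for rep, summits in self.replicate_summits.items():
            write_bed(
                [GenomicInterval(s.chrom, s.pos, s.pos + 1, name=rep)
                 for s in summits],
                out / f"summits_{rep}.bed",
            )
        self.cutrun.to_bedgraph(out / "cutrun.bedGraph")
        self.insertion.to_bedgraph(out / "insertion.bedGraph")
        ctcf = intervals_to_frame(self.ctcf_peaks)
        ctcf["conserved"] = self.ctcf_conserved.astype(int)
        write_table(ctcf, out / "ctcf_peaks.tsv")
        write_table(self.gene_models, out / "genes.tsv")
        write_table(self.rna, out / "rna_de.tsv")
        write_table(self.protein, out / "protein_de.tsv")
        write_table(self.phospho, out / "phospho_de.tsv")
        write_table(
            pd.DataFrame(
                [(tf, g) for tf, gs in self.tf_targets.items()
                 for g in sorted(gs)],
                columns=["tf", "gene"],
            ),
            out / "tf_targets.tsv",
        )
        write_table(self.essential, out / "essential.tsv")
        write_bedpe(self.loops, out / "loops.bedpe")
        write_table(self.loop_contacts, out / "loop_contacts.tsv")
        write_bed(self.tad_boundaries, out / "tad_boundaries.bed")
        write_table(self.cpg_table, out / "cpg.tsv")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name in ("regions", "motif_placements", "genes", "partners",
                     "insulators", "loops", "dmrs"):
            write_table(getattr(self.truth, name), truth_dir / f"{name}.tsv")


# ---------------------------------------------------------------------
# PWMs


def _consensus_pwm(motif_id: str, consensus: str, background,
                   major: float = 0.88) -> PWM:
    minor = (1.0 - major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, base in enumerate(consensus):
        mat[i, _BASES.index(base)] = major
    return PWM(motif_id, mat, np.asarray(background))


def default_pwms(base_comp) -> list[PWM]:
    bg = np.asarray(base_comp)
    return [
        _consensus_pwm("CTCF", CTCF_CONSENSUS, bg),
        _consensus_pwm("PARTNER", PARTNER_CONSENSUS, bg),
        _consensus_pwm("DECOY", DECOY_CONSENSUS, bg),
    ]


def _encode(s: str) -> np.ndarray:
    return np.array([_BASES.index(b) for b in s], dtype=np.int8)


# ---------------------------------------------------------------------
# layout


def _layout_elements(cfg: SimConfig, rng: np.random.Generator):
    """Place region elements and insulator units along the chromosomes.

    Returns (region rows, insulator rows). Insulator units are isolated
    by >= ~55 kb on both sides so that no unrelated gene falls inside
    their 2-50 kb pairing window.
    """
    elements = (
        [("region", "decreased")] * cfg.n_decreased
        + [("region", "increased")] * cfg.n_increased
        + [("region", "control")] * cfg.n_control
        + [("region", "null")] * cfg.n_null
        + [("close_pair", "null")] * cfg.n_close_pairs
        + [("insulator", "increased")] * cfg.n_insulators
    )
    order = rng.permutation(len(elements))
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    cursor = {c: 10_000 for c in chroms}
    regions: list[dict] = []
    insulators: list[dict] = []
    ci = 0
    w = cfg.region_width
    for ei in order:
        kind, cls = elements[ei]
        unit_span = (2 * cfg.insulator_margin + w
                     + cfg.insulator_max_gene_dist + 5000)
        need = unit_span if kind == "insulator" else w + 6000
        placed = False
        for _ in range(cfg.n_chrom):
            chrom = chroms[ci % cfg.n_chrom]
            ci += 1
            if cursor[chrom] + need < cfg.chrom_len - 10_000:
                placed = True
                break
        if not placed:
            raise ValueError("genome too small for requested element count")
        pos = cursor[chrom] + int(rng.integers(1500, 4500))
        if kind == "region":
            regions.append({"chrom": chrom, "start": pos, "end": pos + w,
                            "class": cls})
            cursor[chrom] = pos + w
        elif kind == "close_pair":
            w2 = w // 2
            regions.append({"chrom": chrom, "start": pos, "end": pos + w2,
                            "class": cls, "close_pair": True})
            regions.append({"chrom": chrom, "start": pos + w2 + 50,
                            "end": pos + w2 + 50 + w2, "class": cls,
                            "close_pair": True})
            cursor[chrom] = pos + 2 * w2 + 50
        else:  # insulator unit: DAR ... gene TSS, isolated both sides
            pos = cursor[chrom] + cfg.insulator_margin
            dist = int(rng.integers(cfg.insulator_min_gene_dist,
                                    cfg.insulator_max_gene_dist))
            regions.append({"chrom": chrom, "start": pos, "end": pos + w,
                            "class": "increased", "insulator": True})
            insulators.append(
                {"chrom": chrom, "dar_start": pos, "dar_end": pos + w,
                 "tss": pos + w // 2 + dist, "tss_distance": dist}
            )
            cursor[chrom] = pos + w + dist + cfg.insulator_margin
    regions.sort(key=lambda r: (r["chrom"], r["start"]))
    for i, r in enumerate(regions):
        r["region_index"] = i
        r["name"] = f"nfr_{i:05d}"
        r["summit"] = (r["start"] + r["end"]) // 2
        r.setdefault("close_pair", False)
        r.setdefault("insulator", False)
    return regions, insulators


# ---------------------------------------------------------------------
# genome + motifs


def _plant(codes: np.ndarray, start: int, motif: np.ndarray, strand: str):
    m = motif if strand == "+" else np.array([_COMP[b] for b in motif[::-1]],
                                             dtype=np.int8)
    codes[start : start + len(m)] = m


def _simulate_genome(cfg: SimConfig, rng: np.random.Generator, regions):
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    codes = {
        c: rng.choice(4, size=cfg.chrom_len, p=cfg.base_comp).astype(np.int8)
        for c in chroms
    }
    ctcf = _encode(CTCF_CONSENSUS)
    partner = _encode(PARTNER_CONSENSUS)
    decoy = _encode(DECOY_CONSENSUS)
    placements = []

    used: list[tuple[int, int]] = []  # spans of the current region

    def put(chrom, center, motif, motif_id, strand, role, region_index):
        start = center - len(motif) // 2
        _plant(codes[chrom], start, motif, strand)
        used.append((start, start + len(motif)))
        placements.append(
            {"chrom": chrom, "start": start, "end": start + len(motif),
             "strand": strand, "motif": motif_id, "center": (2 * start + len(motif)) // 2,
             "role": role, "region_index": region_index}
        )

    def free_center(r, width, tries: int = 40) -> int:
        """A uniform motif center inside the region that does not overlap
        any already-planted motif; re-drawn on collision."""
        for _ in range(tries):
            c = r["start"] + int(rng.integers(20, len_r(r) - 20))
            lo, hi = c - width // 2, c - width // 2 + width
            if all(hi <= s or lo >= e for s, e in used):
                return c
        raise ValueError("could not place a motif without overlap")

    def decoy_center(r, ctcf_center, width, allow_right=True,
                     tries: int = 40) -> int:
        """Decoy center at a class-independent distance U(20,150) from the
        CTCF site, on a feasible side (never toward a tandem partner
        site when allow_right is False); re-drawn on collision."""
        for _ in range(tries):
            d = int(rng.integers(20, 151))
            sides = []
            if ctcf_center - d >= r["start"] + 20:
                sides.append(-1)
            if allow_right and ctcf_center + d <= r["end"] - 20:
                sides.append(1)
            if not sides:
                continue
            side = sides[int(rng.integers(0, len(sides)))]
            c = ctcf_center + side * d
            lo, hi = c - width // 2, c - width // 2 + width
            if all(hi <= s or lo >= e for s, e in used):
                return c
        raise ValueError("could not place a decoy motif without overlap")

    for r in regions:
        used = []
        chrom, summit, i = r["chrom"], r["summit"], r["region_index"]
        cls = r["class"]
        strand = "+" if rng.random() < 0.5 else "-"
        r["motif_strand"] = strand
        r["ctcf_center"] = -1
        if cls == "decreased" and not r["close_pair"]:
            r["ctcf_center"] = summit
            put(chrom, summit, ctcf, "CTCF", strand, "primary", i)
            put(chrom, summit + cfg.wide_spacing, ctcf, "CTCF",
                "+" if rng.random() < 0.5 else "-", "wide_pair", i)
            side = 1 if rng.random() < 0.5 else -1
            put(chrom, summit + side * cfg.partner_offset, partner, "PARTNER",
                "+", "partner_near_ctcf", i)
            # keep the decoy off the wide-pair side so its nearest CTCF
            # site is always the primary one
            put(chrom, decoy_center(r, summit, len(decoy), allow_right=False),
                decoy, "DECOY", "+", "decoy", i)
            if rng.random() < cfg.tandem_frac_decreased:
                _put_tandem(put, cfg, rng, chrom, r, ctcf, i)
        elif cls == "increased":
            off = int(rng.normal(cfg.inc_motif_offset, 10))
            side = 1 if rng.random() < 0.5 else -1
            r["ctcf_center"] = summit + side * off
            put(chrom, r["ctcf_center"], ctcf, "CTCF", strand, "primary", i)
            put(chrom, free_center(r, len(partner)), partner, "PARTNER", "+",
                "partner_uniform", i)
            put(chrom, decoy_center(r, r["ctcf_center"], len(decoy)),
                decoy, "DECOY", "+", "decoy", i)
            if rng.random() < cfg.tandem_frac_increased:
                _put_tandem(put, cfg, rng, chrom, r, ctcf, i)
        elif cls == "control" and not r["close_pair"]:
            if rng.random() < cfg.ctrl_motif_frac:
                r["ctcf_center"] = free_center(r, len(ctcf))
                put(chrom, r["ctcf_center"], ctcf, "CTCF", strand,
                    "primary", i)
            put(chrom, free_center(r, len(partner)), partner, "PARTNER", "+",
                "partner_uniform", i)
            if r["ctcf_center"] >= 0:
                put(chrom, decoy_center(r, r["ctcf_center"], len(decoy)),
                    decoy, "DECOY", "+", "decoy", i)
            else:
                put(chrom, free_center(r, len(decoy)), decoy, "DECOY", "+",
                    "decoy", i)
            if rng.random() < cfg.tandem_frac_control:
                _put_tandem(put, cfg, rng, chrom, r, ctcf, i)
    genome = {
        c: "".join(_BASES[b] for b in codes[c]) for c in chroms
    }
    return genome, pd.DataFrame(placements)


def len_r(r) -> int:
    return r["end"] - r["start"]


def _put_tandem(put, cfg, rng, chrom, r, ctcf, i):
    """A ~33 bp tandem CTCF pair (2xCTS) inside the region, away from the
    primary site."""
    c0 = r["start"] + 60
    put(chrom, c0, ctcf, "CTCF", "+", "tandem", i)
    put(chrom, c0 + cfg.tandem_spacing, ctcf, "CTCF",
        "+" if rng.random() < 0.5 else "-", "tandem", i)
    r["has_tandem"] = True


# ---------------------------------------------------------------------
# ATAC counts, peaks, summits


def nb_counts(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """Negative binomial draws with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size, p)


def _simulate_atac(cfg: SimConfig, rng: np.random.Generator, regions):
    n = len(regions)
    base = np.exp(rng.normal(np.log(cfg.mean_count), 0.5, size=n))
    effect = np.zeros(n)
    for i, r in enumerate(regions):
        if r["close_pair"]:
            effect[i] = 0.0
        elif r["class"] == "decreased":
            effect[i] = -cfg.planted_log2fc
        elif r["class"] == "increased":
            effect[i] = cfg.planted_log2fc
        elif r["class"] == "null":
            effect[i] = rng.normal(0.0, 0.5)
        r["planted_log2fc"] = effect[i]
    samples, groups, cols = [], [], []
    for grp, sign in (("ctrl", 0.0), ("trt", 1.0)):
        for rep in range(cfg.n_rep_per_group):
            depth = float(np.exp(rng.normal(0.0, cfg.depth_sd)))
            mu = base * (2.0 ** (effect * sign)) * depth
            cols.append(nb_counts(rng, mu, cfg.dispersion))
            samples.append(f"{grp}_r{rep + 1}")
            groups.append(grp)
    counts = np.stack(cols, axis=1)
    # per-group merged peak calls with q-values encoded as -log10
    group_peaks: dict[str, list[NarrowPeak]] = {"ctrl": [], "trt": []}
    for r in regions:
        iv = GenomicInterval(r["chrom"], r["start"], r["end"], ".", r["name"], 100)
        off = r["summit"] - r["start"]
        cls = r["class"]
        q_ctrl = 6.0 if cls != "increased" else 0.602  # q = 0.25, lenient only
        q_trt = 6.0 if cls != "decreased" else 0.602
        group_peaks["ctrl"].append(NarrowPeak(iv, 10.0, 8.0, q_ctrl, off))
        group_peaks["trt"].append(NarrowPeak(iv, 10.0, 8.0, q_trt, off))
    # group-specific junk peaks, stringent in one group, absent elsewhere;
    # kept clear of real regions so they cannot merge into the reference
    occupied: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        occupied.setdefault(r["chrom"], []).append(
            (r["start"] - 500, r["end"] + 500))
    for grp in ("ctrl", "trt"):
        for j in range(50):
            for _ in range(100):
                chrom = f"chr{int(rng.integers(1, cfg.n_chrom + 1))}"
                pos = int(rng.integers(20_000, cfg.chrom_len - 20_000))
                if all(pos + 200 <= s or pos >= e
                       for s, e in occupied.get(chrom, [])):
                    break
            # junk must not overlap other junk either, or a stringent
            # ctrl/trt pair would look reproducible
            occupied.setdefault(chrom, []).append((pos - 100, pos + 300))
            iv = GenomicInterval(chrom, pos, pos + 200, ".",
                                 f"junk_{grp}_{j}", 50)
            group_peaks[grp].append(NarrowPeak(iv, 5.0, 6.0, 6.0, 100))
    # per-replicate summits jittered around the true center
    replicate_summits: dict[str, list[Summit]] = {}
    for s, grp in zip(samples, groups):
        lst = []
        for r in regions:
            pos = int(np.clip(
                round(r["summit"] + rng.normal(0, cfg.summit_jitter)),
                r["start"] + 5, r["end"] - 6,
            ))
            lst.append(Summit(r["chrom"], pos))
        replicate_summits[s] = lst
    return counts, samples, np.array(groups), group_peaks, replicate_summits


# ---------------------------------------------------------------------
# tracks


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _simulate_cutrun(cfg: SimConfig, rng: np.random.Generator, regions):
    """Occupancy bedGraph at 10-bp bins around CTCF sites.

    Decreased sites get a single bump offset upstream of the motif
    (strand-aware); averaged without orientation this yields a double
    summit. Increased sites get a strong symmetric bump at the motif.
    """
    binsize = 10
    data: dict[str, list[tuple[int, np.ndarray]]] = {}
    half = 600
    for r in regions:
        if r["ctcf_center"] < 0 or r["close_pair"]:
            continue
        chrom, c = r["chrom"], r["ctcf_center"]
        lo = (c - half) // binsize * binsize
        centers = np.arange(lo, c + half, binsize) + binsize / 2
        if r["class"] == "decreased":
            sign = -1 if r["motif_strand"] == "+" else 1
            amp = cfg.occupancy_amp * rng.uniform(0.8, 1.2)
            vals = amp * _gauss(centers, c + sign * cfg.occupancy_offset,
                                cfg.occupancy_sigma)
        elif r["class"] == "increased":
            amp = cfg.inc_occupancy_amp * rng.uniform(0.8, 1.2)
            vals = amp * _gauss(centers, c, cfg.occupancy_sigma)
        else:  # control: weak symmetric binding
            amp = 0.3 * cfg.occupancy_amp * rng.uniform(0.8, 1.2)
            vals = amp * _gauss(centers, c, cfg.occupancy_sigma)
        data.setdefault(chrom, []).append((lo, vals))
    return _segments_to_track(data, binsize)


def _simulate_insertion(cfg: SimConfig, rng: np.random.Generator, regions):
    """Per-base Tn5 insertion counts around motif sites.

    Bound CTCF motifs (decreased regions) show flanking insertion
    summits and a protected core; decoy motifs sit in uniform insertion
    background.
    """
    data: dict[str, list[tuple[int, np.ndarray]]] = {}
    pad = 150
    motif_half = len(CTCF_CONSENSUS) // 2
    for r in regions:
        if r["close_pair"] or r["class"] not in ("decreased", "control"):
            continue
        chrom = r["chrom"]
        lo, hi = r["start"] - pad, r["end"] + pad
        x = np.arange(lo, hi)
        lam = np.full(len(x), cfg.insertion_base)
        if r["class"] == "decreased":
            # bound CTCF: flanking insertion summits, protected core
            c = r["ctcf_center"]
            lam = lam * (
                1.0
                + cfg.flank_amp * _gauss(x, c - 40, 12.0)
                + cfg.flank_amp * _gauss(x, c + 40, 12.0)
            )
            lam[np.abs(x - c) <= motif_half] *= cfg.protection_depth
        vals = rng.poisson(lam).astype(float)
        data.setdefault(chrom, []).append((lo, vals))
    return _segments_to_track(data, 1)


def _segments_to_track(data, binsize) -> SignalTrack:
    """Overlap-add binsize-aligned piecewise segments into a SignalTrack."""
    track = {}
    for chrom, segs in data.items():
        allpos = np.concatenate([lo + np.arange(len(v)) * binsize
                                 for lo, v in segs])
        allval = np.concatenate([v for _, v in segs])
        uniq, inv = np.unique(allpos, return_inverse=True)
        acc = np.zeros(len(uniq))
        np.add.at(acc, inv, allval)
        keep = acc != 0
        if np.any(keep):
            track[chrom] = (uniq[keep], uniq[keep] + binsize, acc[keep])
    return SignalTrack(track)


# ---------------------------------------------------------------------
# omics


def _de_table(rng, features, effects, se) -> pd.DataFrame:
    obs = np.asarray(effects) + rng.normal(0.0, se, size=len(features))
    z = obs / se
    p = 2.0 * _norm.sf(np.abs(z))
    return pd.DataFrame(
        {"feature": features, "log2fc": obs, "p": p, "q": bh_adjust(p)}
    )


def _simulate_omics(cfg: SimConfig, rng: np.random.Generator, regions,
                    insulators):
    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    n_plain = cfg.n_genes - cfg.n_tfs
    gene_ids = [f"G{i + 1:04d}" for i in range(n_plain)] + tf_ids
    rna_eff = {g: 0.0 for g in gene_ids}
    prot_eff = {g: 0.0 for g in gene_ids}
    roles = {g: "background" for g in gene_ids}

    # insulator genes: strongly upregulated
    ins_rows = []
    for k, ins in enumerate(insulators):
        g = f"G{k + 1:04d}"
        rna_eff[g] = cfg.insulator_effect
        roles[g] = "insulator"
        ins_rows.append({**ins, "gene": g})
    n_used = len(insulators)

    # genes linked to DAR promoters (TSS inside the region)
    gene_pos: dict[str, tuple[str, int, str]] = {}
    for ins in ins_rows:
        gene_pos[ins["gene"]] = (ins["chrom"], ins["tss"], "+")
    for r in regions:
        if r["close_pair"] or r.get("insulator"):
            continue
        if r["class"] in ("decreased", "increased", "control") and \
                rng.random() < cfg.dar_gene_frac and n_used < n_plain - 300:
            g = f"G{n_used + 1:04d}"
            n_used += 1
            tss = int(rng.integers(r["start"] + 50, r["end"] - 50))
            gene_pos[g] = (r["chrom"], tss, "+" if rng.random() < 0.5 else "-")
            r["linked_gene"] = g
            if r["class"] == "decreased" and rng.random() < 0.6:
                rna_eff[g] = -cfg.dar_gene_effect
                roles[g] = "dar_down"
            elif r["class"] == "increased" and rng.random() < 0.6:
                rna_eff[g] = cfg.dar_gene_effect
                roles[g] = "dar_up"
            else:
                roles[g] = "dar_null"

    # partner TFs and their target regulons
    partner_layers = {
        "TF01": ("rna_down", "protein_down"),
        "TF02": ("protein_up",),
        "TF03": ("rna_up",),
        "TF04": ("rna_down",),
        "TF05": ("protein_down",),
        "TF06": ("rna_up", "protein_up"),
        "TF07": ("rna_down",),
        "TF08": ("protein_up",),
    }
    partner_own = {  # evident partners move themselves; hidden stay flat
        "TF01": {"rna": -1.5, "protein": -1.2},
        "TF02": {"protein": -1.2},
        "TF03": {"phospho": -1.5},
        "TF04": {"rna": 1.2},
        "TF05": {}, "TF06": {}, "TF07": {}, "TF08": {},
    }
    partners = list(partner_layers)[: cfg.n_partners]
    free_pool = [g for g in gene_ids[:n_plain] if roles[g] == "background"]
    rng.shuffle(free_pool)
    tf_targets: dict[str, set[str]] = {}
    cursor = 0
    for tf in tf_ids:
        if tf in partners:
            targets = set(free_pool[cursor : cursor + cfg.targets_per_tf])
            cursor += cfg.targets_per_tf
            for layer in partner_layers[tf]:
                sign = 1.0 if layer.endswith("up") else -1.0
                for g in targets:
                    if layer.startswith("rna"):
                        rna_eff[g] = sign * cfg.target_effect
                    else:
                        prot_eff[g] = sign * cfg.target_effect
            for g in targets:
                roles[g] = f"target_{tf}"
        else:
            targets = set(rng.choice(gene_ids, size=cfg.targets_per_tf,
                                     replace=False))
        tf_targets[tf] = targets
    for tf, own in partner_own.items():
        if tf not in partners:
            continue
        rna_eff[tf] = own.get("rna", 0.0)
        prot_eff[tf] = own.get("protein", 0.0)

    # gene models: every gene gets a TSS; unplaced genes go to free space,
    # steering clear of insulator units (their 2-50 kb pairing windows
    # must contain only the planted gene)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    exclusion: dict[str, list[tuple[int, int]]] = {}
    for ins in ins_rows:
        exclusion.setdefault(ins["chrom"], []).append(
            (ins["dar_start"] - cfg.insulator_margin,
             ins["tss"] + cfg.insulator_margin))
    rows = []
    for g in gene_ids:
        if g in gene_pos:
            chrom, tss, strand = gene_pos[g]
        else:
            for _ in range(100):
                chrom = chroms[int(rng.integers(0, cfg.n_chrom))]
                tss = int(rng.integers(20_000, cfg.chrom_len - 20_000))
                if all(tss <= s or tss >= e
                       for s, e in exclusion.get(chrom, [])):
                    break
            strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"gene": g, "chrom": chrom, "tss": tss, "strand": strand})
    gene_models = pd.DataFrame(rows)

    rna = _de_table(rng, gene_ids, [rna_eff[g] for g in gene_ids], cfg.omics_se)
    # protein layer covers most genes; TF49+ deliberately not MS-detected
    undetected = set(tf_ids[48:])
    prot_genes = [
        g for g in gene_ids
        if g not in undetected and (g in tf_ids or rng.random() < 0.75)
    ]
    prot = _de_table(rng, prot_genes, [prot_eff[g] for g in prot_genes],
                     cfg.omics_se)
    # phosphopeptides: two per detected TF
    pep_rows, pep_eff = [], []
    phospho_own = {"TF03": -1.5}
    for tf in tf_ids:
        if tf in undetected:
            continue
        for k in (1, 2):
            pep_rows.append({"feature": f"{tf}_p{k}", "gene": tf})
            pep_eff.append(phospho_own.get(tf, 0.0) if k == 1 else 0.0)
    phospho = _de_table(rng, [r["feature"] for r in pep_rows], pep_eff,
                        cfg.omics_se)
    phospho["gene"] = [r["gene"] for r in pep_rows]

    essential_set = {"TF01", "TF03", "TF05", "TF06", "TF07", "TF08"} | {
        f"TF{i:02d}" for i in range(10, 16)
    }
    essential = pd.DataFrame(
        {
            "gene": tf_ids,
            "score": [0.005 if tf in essential_set else 0.5 for tf in tf_ids],
        }
    )
    truth_partners = pd.DataFrame(
        {
            "tf": partners,
            "kind": ["evident" if partner_own[tf] else "hidden"
                     for tf in partners],
            "layers": [";".join(partner_layers[tf]) for tf in partners],
        }
    )
    truth_genes = pd.DataFrame(
        {
            "gene": gene_ids,
            "rna_effect": [rna_eff[g] for g in gene_ids],
            "protein_effect": [prot_eff[g] for g in gene_ids],
            "role": [roles[g] for g in gene_ids],
        }
    )
    return (gene_models, rna, prot, phospho, tf_targets, essential,
            truth_partners, truth_genes, pd.DataFrame(ins_rows))


# ---------------------------------------------------------------------
# loops, TADs, methylation


def _simulate_loops(cfg: SimConfig, rng: np.random.Generator, regions,
                    ins_rows):
    loops: list[LoopRecord] = []
    rows = []
    loss_by_class = {
        "decreased": cfg.loop_loss_decreased,
        "control": cfg.loop_loss_control,
        "increased": cfg.loop_loss_increased,
    }
    region_spans: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        region_spans.setdefault(r["chrom"], []).append((r["start"], r["end"]))
    candidates = [r for r in regions
                  if r["class"] in loss_by_class and not r["close_pair"]
                  and not r.get("insulator")]
    by_class: dict[str, list] = {}
    for r in candidates:
        by_class.setdefault(r["class"], []).append(r)
    li = 0
    for cls, pool in by_class.items():
        pick = rng.choice(len(pool), size=min(cfg.loops_per_class, len(pool)),
                          replace=False)
        for j in pick:
            r = pool[int(j)]
            a1 = GenomicInterval(r["chrom"], r["start"], r["end"])
            spans = region_spans.get(r["chrom"], [])
            for _ in range(50):
                far = min(r["end"] + int(rng.integers(80_000, 200_000)),
                          cfg.chrom_len - 5000)
                if all(far + 2000 <= s or far >= e for s, e in spans):
                    break
            a2 = GenomicInterval(r["chrom"], far, far + 2000)
            lfc = loss_by_class[cls] + rng.normal(0.0, cfg.loop_loss_sd)
            c0 = float(np.exp(rng.normal(np.log(cfg.loop_contact_mean), 0.2)))
            loops.append(LoopRecord(a1, a2, f"loop_{li:04d}"))
            rows.append({"loop": f"loop_{li:04d}", "anchor_class": cls,
                         "contact_ctrl": c0, "contact_trt": c0 * 2.0 ** lfc,
                         "planted_log2fc": lfc})
            li += 1
    for ins in ins_rows.to_dict("records"):
        a1 = GenomicInterval(ins["chrom"], ins["dar_start"], ins["dar_end"])
        a2 = GenomicInterval(ins["chrom"], max(0, ins["tss"] - 1000),
                             ins["tss"] + 1000)
        lfc = cfg.loop_loss_increased + rng.normal(0.0, cfg.loop_loss_sd)
        c0 = float(np.exp(rng.normal(np.log(cfg.loop_contact_mean), 0.2)))
        loops.append(LoopRecord(a1, a2, f"loop_{li:04d}"))
        rows.append({"loop": f"loop_{li:04d}", "anchor_class": "insulator",
                     "contact_ctrl": c0, "contact_trt": c0 * 2.0 ** lfc,
                     "planted_log2fc": lfc})
        li += 1
    return loops, pd.DataFrame(rows)


def _simulate_boundaries(cfg: SimConfig, rng: np.random.Generator, regions):
    """TAD boundaries planted near a fraction of control and decreased
    regions; increased regions stay distal."""
    out = []
    k = 0
    for r in regions:
        if r["close_pair"]:
            continue
        if r["class"] in ("control", "decreased") and \
                rng.random() < cfg.boundary_frac:
            c = r["summit"] + int(rng.normal(0, 300))
            out.append(GenomicInterval(r["chrom"], max(0, c - 500), c + 500,
                                       name=f"boundary_{k:04d}"))
            k += 1
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def _simulate_methylation(cfg: SimConfig, rng: np.random.Generator, regions):
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    rows_pos, rows_chrom = [], []
    for c in chroms:
        n = cfg.chrom_len // cfg.cpg_spacing
        pos = (np.arange(n) * cfg.cpg_spacing
               + rng.integers(0, cfg.cpg_spacing, size=n))
        rows_pos.append(pos)
        rows_chrom.extend([c] * n)
    pos = np.concatenate(rows_pos)
    chrom = np.array(rows_chrom)
    n = len(pos)
    mu = np.clip(cfg.meth_mean + rng.normal(0, 0.08, size=n), 0.05, 0.95)
    mu_ctrl = mu.copy()
    mu_trt = mu.copy()
    # planted DMRs in free space (away from regions): pick CpG runs whose
    # span avoids all region windows by >= 2 kb
    occupied = []
    for r in regions:
        occupied.append((r["chrom"], r["start"] - 2000, r["end"] + 2000))
    occ_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in occupied:
        occ_by_chrom.setdefault(c, []).append((s, e))
    dmr_rows = []
    tries = 0
    while len(dmr_rows) < cfg.n_dmrs and tries < 2000:
        tries += 1
        i = int(rng.integers(0, n - cfg.dmr_n_cpg))
        if chrom[i] != chrom[i + cfg.dmr_n_cpg - 1]:
            continue
        span_lo, span_hi = pos[i], pos[i + cfg.dmr_n_cpg - 1]
        if any(s < span_hi and span_lo < e
               for s, e in occ_by_chrom.get(chrom[i], [])):
            continue
        if any(d["chrom"] == chrom[i] and abs(d["start"] - span_lo) < 5000
               for d in dmr_rows):
            continue
        # tight CpG cluster with a clean shift in the treated condition
        cluster = pos[i] + np.arange(cfg.dmr_n_cpg) * cfg.dmr_cpg_gap
        pos[i : i + cfg.dmr_n_cpg] = cluster
        # hyper DMRs rise from a partially methylated base; hypo DMRs
        # drop from the near-fully-methylated background
        sign = 1.0 if rng.random() < 0.5 else -1.0
        base = 0.55 if sign > 0 else 0.95
        mu_ctrl[i : i + cfg.dmr_n_cpg] = base
        mu_trt[i : i + cfg.dmr_n_cpg] = base + sign * cfg.dmr_delta
        dmr_rows.append(
            {"chrom": chrom[i], "start": int(cluster[0]),
             "end": int(cluster[-1]) + 1, "n_cpg": cfg.dmr_n_cpg,
             "delta": sign * cfg.dmr_delta}
        )
    prec = cfg.meth_precision
    theta_c = rng.beta(mu_ctrl * prec, (1 - mu_ctrl) * prec)
    theta_t = rng.beta(mu_trt * prec, (1 - mu_trt) * prec)
    cov_c = rng.poisson(cfg.meth_coverage, size=n)
    cov_t = rng.poisson(cfg.meth_coverage, size=n)
    meth_c = rng.binomial(cov_c, theta_c)
    meth_t = rng.binomial(cov_t, theta_t)
    order = np.lexsort((pos, chrom))
    cpg = pd.DataFrame(
        {
            "chrom": chrom[order],
            "pos": pos[order],
            "meth_ctrl": meth_c[order],
            "total_ctrl": cov_c[order],
            "meth_trt": meth_t[order],
            "total_trt": cov_t[order],
        }
    )
    return cpg, pd.DataFrame(dmr_rows,
                             columns=["chrom", "start", "end", "n_cpg", "delta"])


# ---------------------------------------------------------------------
# top level


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate the full synthetic study under one seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    regions, insulators = _layout_elements(cfg, rng)
    genome, placements = _simulate_genome(cfg, rng, regions)
    counts, samples, groups, group_peaks, rep_summits = _simulate_atac(
        cfg, rng, regions)
    cutrun = _simulate_cutrun(cfg, rng, regions)
    insertion = _simulate_insertion(cfg, rng, regions)
    (gene_models, rna, prot, phospho, tf_targets, essential,
     truth_partners, truth_genes, ins_rows) = _simulate_omics(
        cfg, rng, regions, insulators)
    loops, loop_contacts = _simulate_loops(cfg, rng, regions, ins_rows)
    boundaries = _simulate_boundaries(cfg, rng, regions)
    cpg, truth_dmrs = _simulate_methylation(cfg, rng, regions)

    region_ivs = [
        GenomicInterval(r["chrom"], r["start"], r["end"], ".", r["name"])
        for r in regions
    ]
    # CTCF occupancy peaks: at every planted primary CTCF site
    ctcf_peaks, conserved = [], []
    decoy_budget = 30
    for r in regions:
        if r["ctcf_center"] < 0 or r["close_pair"]:
            continue
        ctcf_peaks.append(
            GenomicInterval(r["chrom"], r["ctcf_center"] - 150,
                            r["ctcf_center"] + 150,
                            name=f"ctcf_{r['region_index']:05d}")
        )
        if r.get("insulator"):
            conserved.append(True)
        elif r["class"] == "decreased" and decoy_budget > 0:
            conserved.append(True)  # conserved site in a non-increased DAR
            decoy_budget -= 1
        else:
            conserved.append(False)

    truth_regions = pd.DataFrame(
        [
            {
                "region_index": r["region_index"],
                "name": r["name"],
                "chrom": r["chrom"],
                "start": r["start"],
                "end": r["end"],
                "class": r["class"],
                "summit": r["summit"],
                "planted_log2fc": r.get("planted_log2fc", 0.0),
                "ctcf_center": r["ctcf_center"],
                "motif_strand": r.get("motif_strand", "."),
                "has_tandem": bool(r.get("has_tandem", False)),
                "close_pair": r["close_pair"],
                "insulator": r.get("insulator", False),
                "linked_gene": r.get("linked_gene", ""),
            }
            for r in regions
        ]
    )
    truth = Truth(
        regions=truth_regions,
        motif_placements=placements,
        genes=truth_genes,
        partners=truth_partners,
        insulators=pd.DataFrame(ins_rows),
        loops=loop_contacts.copy(),
        dmrs=truth_dmrs,
    )
    return SimulatedStudy(
        config=cfg,
        truth=truth,
        genome=genome,
        pwms=default_pwms(cfg.base_comp),
        regions=region_ivs,
        counts=counts,
        samples=samples,
        groups=groups,
        group_peaks=group_peaks,
        replicate_summits=rep_summits,
        cutrun=cutrun,
        insertion=insertion,
        ctcf_peaks=ctcf_peaks,
        ctcf_conserved=np.array(conserved, dtype=bool),
        gene_models=gene_models,
        rna=rna,
        protein=prot,
        phospho=phospho,
        tf_targets=tf_targets,
        essential=essential,
        loops=loops,
        loop_contacts=loop_contacts,
        tad_boundaries=boundaries,
        cpg_table=cpg,
    )


# -- focused count simulators (engine calibration) ---------------------


def simulate_null_counts(
    n_features: int,
    n_rep: int = 3,
    dispersion: float = 0.1,
    mean_log: float = np.log(100.0),
    mean_sd: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """NB count matrix with identical group means (null features)."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(mean_log, mean_sd, size=n_features))
    return nb_counts(rng, np.tile(base[:, None], (1, 2 * n_rep)), dispersion)


def simulate_planted_counts(
    n_features: int,
    frac_changed: float = 0.1,
    log2fc: float = 2.0,
    n_rep: int = 3,
    dispersion: float = 0.1,
    mean_log: float = np.log(100.0),
    mean_sd: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """NB counts with a fraction of features shifted in the second group
    (random sign). Returns (counts, planted signed log2fc)."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(mean_log, mean_sd, size=n_features))
    effect = np.zeros(n_features)
    n_changed = int(round(frac_changed * n_features))
    idx = rng.choice(n_features, size=n_changed, replace=False)
    effect[idx] = log2fc * rng.choice([-1.0, 1.0], size=n_changed)
    mu = np.tile(base[:, None], (1, 2 * n_rep)).astype(float)
    mu[:, n_rep:] *= 2.0 ** effect[:, None]
    return nb_counts(rng, mu, dispersion), effect
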