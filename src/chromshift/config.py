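"""Run configuration: every analysis threshold as a named, documented key.

Defaults are the study's stated cutoffs: FDR 0.05 and 2-fold change for
differential regions, raw p > 0.5 and fold change < 1.05 for control
regions, TSS +/- 2 kb promoters, 2-50 kb insulator search window, ~33 bp
tandem CTCF-site spacing, 500 bp minimum summit separation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # differential classification
    fc_cut: float = 2.0
    q_cut: float = 0.05
    ctrl_p: float = 0.5
    ctrl_fc: float = 1.05
    # peaks
    stringent_q: float = 0.05
    lenient_q: float = 0.5
    min_summit_separation: int = 500
    target_fragments: int = 20_000_000
    # motifs
    motif_pseudo: float = 1e-4
    motif_thresh_p: float = 1e-4
    tandem_max_gap: int = 35
    # profiles
    heatmap_half_width: int = 1000
    heatmap_bin: int = 10
    cluster_half_width: int = 250
    kmeans_k: int = 4
    kmeans_n_init: int = 10
    footprint_half_width: int = 100
    # methylation
    meth_min_cov: int = 5
    dmr_p: float = 0.01
    dmr_min_len: int = 50
    dmr_min_cpg: int = 3
    dmr_max_gap: int = 200
    # integration
    promoter_half: int = 2000
    insulator_min_dist: int = 2000
    insulator_max_dist: int = 50_000
    gsea_permutations: int = 1000
    # coregulators
    partner_enr_fdr: float = 0.05
    partner_own_fdr: float = 0.05
    # plumbing
    seed: int = 0
    outdir: str = "chromshift_out"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and f.name not in ("seed",):
                if not (v > 0 and v == v and abs(v) != float("inf")):
                    raise ValueError(f"config field {f.name} must be positive and finite")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
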