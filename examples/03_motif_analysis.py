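"""PWM scanning with exact p-values, summit-to-motif distances and
tandem CTCF sites (2xCTS).

Decreased regions carry a CTCF motif at the summit, increased regions
~100 bp away, and control regions usually none nearby — so the median
nearest-motif distance orders decreased < increased < control, the
pattern that links accessibility loss to direct CTCF occupancy.
"""

import numpy as np

from chromshift import SimConfig, simulate_study
from chromshift.difftest import (classify_features, moderated_test,
                                 tmm_factors)
from chromshift.intervals import Summit
from chromshift.motifs import nearest_motif_distance, scan_pwm, tandem_sites
from chromshift.peaks import refine_summits

study = simulate_study(SimConfig(seed=1))
table = classify_features(moderated_test(
    study.counts, tmm_factors(study.counts), study.groups, "ctrl", "trt",
    feature_ids=[iv.name for iv in study.regions]))
cls = dict(zip(table["feature"], table["class"]))

summits = [s for lst in study.replicate_summits.values() for s in lst]
kept, _ = refine_summits(study.regions, summits, 500)

hits = scan_pwm(study.genome, study.pwms[0], threshold_p=1e-4)
print(f"CTCF hits across the genome: {len(hits)}")

for klass in ("decreased", "increased", "control"):
    anchors = [Summit(s.chrom, s.pos) for r, s in kept
               if cls[r.name] == klass]
    d = nearest_motif_distance(anchors, hits)["distance"]
    print(f"{klass:>10}: n={len(d):4d}  median nearest-CTCF distance "
          f"{np.median(d):8.1f} bp")

tandems = tandem_sites(hits, max_gap=35)
print(f"tandem CTCF sites (gap <= 35 bp): {len(tandems)}")
# The ~0 bp median for decreased regions and ~100 bp for increased
# regions reproduce the geometry planted by the generator.
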