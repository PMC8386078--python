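"""Generate the synthetic acute-depletion study and look at what was
planted.

The generator builds a 4 x 2 Mb genome carrying ~1300 nucleosome-free
regions with known accessibility classes, CTCF/partner/decoy motif
placements, occupancy and insertion tracks, multi-omics differential
tables, loops, TAD boundaries and CpG methylation — all with a truth
table for later recovery checks.
"""

from chromshift import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))

truth = study.truth.regions
print(f"genome: {len(study.genome)} chromosomes x "
      f"{study.config.chrom_len // 1_000_000} Mb")
print(f"regions: {len(study.regions)} "
      f"({truth['class'].value_counts().to_dict()})")
print(f"planted insulator genes: {len(study.truth.insulators)}")
print(f"planted partner TFs: {study.truth.partners['tf'].tolist()}")
print(f"planted DMRs: {len(study.truth.dmrs)}")
print(f"loops: {len(study.loops)}, TAD boundaries: "
      f"{len(study.tad_boundaries)}, CpGs: {len(study.cpg_table)}")
# The class counts are the planted ground truth that the differential
# stage (example 02) must recover from the negative-binomial counts.
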