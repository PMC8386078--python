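# Methods

This note documents the models, parameter choices and numerical
conventions behind `chromshift`, and what the synthetic study does and
does not establish.

## Coordinates and formats

All positions are 0-based half-open (BED convention) throughout;
`intervals.to_one_based` is the single conversion point for display.
Overlap always means ≥ 1 bp. Strand "." is treated as "+" where an
orientation is required (the only orientation the analyses need is the
motif strand, which is always explicit). Interval queries use sorted
arrays with a running-maximum-of-ends bound rather than a tree; the
collections here are static and small, and the brute-force oracle tests
cover the implementation.

## Reference NFRs and summits

A peak is reproducible iff it is stringent (q ≤ 0.05) in its own group
and overlapped by at least a lenient call (q ≤ 0.5) in every other
group; reproducible peaks from all groups are interval-merged. q-values
arrive in narrowPeak column 9 as −log₁₀(q). Summit refinement picks,
per region, the replicate summit minimizing |pos − center| with ties to
the smaller position; the region center of an even-length region is
⌊(start+end)/2⌋. Chosen summits closer than `min_summit_separation`
(default 500 bp, the k-means window size) are removed **pairwise — both
members** — a convention chosen because the artifact the filter guards
against (overlapping heatmap rows) affects both summits; it is
configurable.

## Differential testing

Normalization is trimmed mean of M-values computed on **raw counts**
against the sample whose library size is closest to the median, with
30% log-ratio and 5% intensity trimming and inverse asymptotic-variance
weights; the resulting factors therefore absorb both library size and
composition (normalized counts are `x / factor`), and are rescaled to
geometric mean 1. For a column exactly doubled, the factors are
(1/√2, √2).

The test is a precision-weighted moderated t: log₂-CPM with 0.5-count
offset against effective sizes `factor × geomean(lib)`; a first
unweighted fit gives residual standard deviations whose quarter-roots
are lowess-smoothed (span 0.5, 3 robustifying iterations) against mean
log count; interpolating the trend at each observation's fitted log
count gives weights `sd⁻⁴`; a weighted two-group fit follows; residual
variances are shrunk toward a scaled inverse-χ² prior whose (d₀, s₀²)
come from a method-of-moments fit on log-variances (trigamma inversion
by Newton), with d₀ clamped to (0, 10⁶]. The moderated t has
d_residual + d₀ degrees of freedom; p-values are BH-adjusted. Setting
the prior weight to zero recovers the ordinary weighted t exactly, and
a small-matrix cross-check against edgeR TMM + limma-voom (run through
Rscript in the test suite) agrees to a few percent on factors and
> 0.99 rank correlation on statistics.

Classification: decreased/increased at q < 0.05 and |log₂FC| > 1;
control at **raw** p > 0.5 and max(FC, 1/FC) < 1.05 (the symmetric
reading of "fold change < 1.05"; raw rather than adjusted p is the
literal reading of the stated control cutoff — both are configurable).

## Motif scanning

The pseudo-probability convention is `p' = (p + λ·bg) / (1 + λ)` with
λ = 10⁻⁴; scores are log₂(p'/bg) summed over positions, N bases
contributing 0. Exact match p-values come from the distribution of the
window score under the background base composition, computed by dynamic
programming over scores discretized to 10⁻³ bins; the accumulated
rounding is ≤ L·5×10⁻⁴ in score, negligible at motif lengths used here
(tests bracket the enumeration accordingly). Hits are windows with
p ≤ 10⁻⁴ on either strand; minus-strand hits are scored with the
reverse-complement matrix and reported in forward coordinates. PWMs of
length ≥ 3 are accepted. Overlapping self-hits are kept: every counting
unit downstream is "region has ≥ 1 hit", which pruning cannot change.

Orientation: the nearest hit decides the flip (distance ties broken by
higher score, then leftmost start, then "+"). Tandem sites are maximal
runs of ≥ 2 hits with successive center gaps ≤ 35 bp (the ~33 bp
spacing of tandem CTCF sites), any strand combination. Fisher p-values
are two-sided by the point-probability rule, implemented vectorized via
log-binomial coefficients and verified against full enumeration for all
tables with row margins ≤ 30.

## Profiles and footprints

Profile matrices are step-function integrals (exact bin means, not
sampled points); windows crossing position 0 are zero-padded and
counted. Rows are max-normalized before k-means (shape, not amplitude;
zero rows dropped), the best of `n_init = 10` seeded restarts is kept,
and cluster labels are renumbered by descending mean raw signal. The
single/double call uses peak prominence ≥ 0.3 × max and ≥ 5-bin (50 bp)
separation, with −∞ padding so edge maxima count; the default
double-summit window is ±250 bp at 10 bp bins, the heatmap window
±1 kb. Upstream bias is the median of per-row upstream/downstream sum
ratios (one-sided rows capped at 10⁶) with an exact two-sided sign
test. The footprint protection ratio is the larger flanking summit of
the aggregated, strand-oriented per-base insertion profile divided by
the mean over the central motif-width span.

## Methylation

Replicates are pooled by summing counts upstream (single-clone design).
The per-CpG test is a two-sided Fisher exact on the
methylated/unmethylated 2×2 — assumption-free at the ~30× coverages
involved, at the cost of ignoring cross-CpG smoothing; CpGs under 5×
in either condition are excluded. DMRs merge significant CpGs (p ≤
0.01, |Δ| > 0, consistent sign, successive gaps ≤ 200 bp — the gap is a
package choice) into runs with ≥ 3 CpGs over ≥ 50 bp. Direction is
recorded; "change > 0" is read as |Δ| > 0. Meta-profiles weight each
CpG by coverage and report empty bins as missing, never zero.

## Integration and co-regulators

Promoters are TSS ± 2 kb; insulator discovery measures the 2–50 kb
distance from the refined DAR **summit** to the TSS (the summit being
the representative point) and reports one candidate per gene, the
nearest qualifying DAR; loop support requires the two anchors of one
loop to overlap the DAR and the promoter window separately. The
"conserved CTCF motif" property is consumed as an input flag on CTCF
peaks; no conservation is computed. Loop grouping precedence when a
loop touches several classes is decreased > increased > control
(flagged); loops touching only unclassified regions are excluded. GSEA
uses the weighted-KS running sum with a gene-label permutation null
(1000 permutations, seeded; there is only one contrast, so phenotype
permutation is unavailable); NES divides by the mean |null ES| of the
same sign. Partner classification requires a BH-corrected (per
layer × direction, across TFs) hypergeometric target enrichment
FDR < 0.05 **and** MS detection; evident partners additionally have an
own-change FDR < 0.05 in any of mRNA/protein/phospho (phospho
summarized as the minimum across the TF's peptides; absence from a
layer is missing, not 1.0). All 2×2 odds ratios use a Haldane 0.5
correction only when a cell is zero, flagged.

## The synthetic study

Defaults: 4 chromosomes × 2 Mb at human-like base composition
(29.5/20.5/20.5/29.5), 350 decreased + 350 increased + 350 control +
250 null regions of 500 bp, 12 isolated insulator units, 12 close
summit pairs, 800 genes (60 of them TFs, 8 planted partners: 4 evident,
4 hidden with 30-gene regulons), 150 loops per class, ~53k CpGs at
~150 bp spacing, 20 DMRs. Counts are negative binomial (dispersion
0.03, mean ≈ 300 — clonal-line ATAC replicates; the engine-calibration
simulations use the harsher dispersion 0.1 at mean ≈ 100) with planted
4-fold shifts; omics effect estimates are normal with SE 0.25;
methylation is beta-binomial (precision 200, coverage Poisson(30));
loop contact losses are −1.5/−0.5/−0.2 log₂ (sd 0.2) for
decreased/control/increased anchors. Motif geometry: decreased regions
carry CTCF at the summit, a second CTCF 200 bp away, a partner motif
40 bp from the site; increased regions carry CTCF ~100 bp off-summit
and, in 15.4% of cases, a 33 bp tandem pair (2.4% of controls, 1.4% of
decreased, matching the published fractions); the decoy motif is always
placed at a distance drawn identically (U(20, 150) bp from the CTCF
site) in every class so that its pairwise-distance comparison is null
by construction. Occupancy bumps sit 150 bp upstream of the motif on a
random strand; hyper DMRs rise 0.55 → 0.95 and hypo DMRs fall
0.95 → 0.55 (|Δ| = 0.4). A single integer seed drives one PCG64 stream.

What passing recovery tests shows — and does not. The generator plants
clean, well-separated effects: real ATAC data has copy-number and
GC artifacts, overlapping peaks, fragmented regulons, motif databases
with correlated PWMs, and smoothing-worthy methylation dispersion, none
of which are emulated. Recovery here demonstrates that the pipeline's
rules implement the intended selections and that the statistics are
calibrated (type-I error ≈ 0.05, BH FDR held, GSEA permutation p
uniform under null draws); it does not certify genome-scale performance
on real libraries. Problem sizes were chosen so the entire suite and
the acceptance script each run in about a minute on one core.

## Known limitations

- Two-group designs only; no batch covariates in the moderated test.
- The DMR caller does not smooth; very low-coverage designs would favor
  a shrinkage-based site test.
- The exact-p scanner assumes an i.i.d. background; CpG islands and
  repeats violate this on real genomes.
- BigWig is not read or written; bedGraph stands in for signal tracks.
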