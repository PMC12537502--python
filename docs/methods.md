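# Methods

This note records the models implemented, the parameters that matter, what
the synthetic-data generators do and do not emulate, and the design
decisions taken where the procedure was genuinely open.

## Coordinates and inputs

All internal intervals are 0-based half-open (BED-native); GFF3 is
converted on read (start−1) and restored on write. A Tn5 insertion is a
single base: plus-strand reads yield `start + 4`, minus-strand reads the
5′ end of the read (`end − 1`) shifted by −5. Fragments-TSV rows carry
(chrom, start, end, barcode, count); each row expands to `count`
insertion events at the fragment start with `frag_size = end − start`.

Nucleus QC keeps barcodes with ≥1,000 insertions, TSS fraction > 0.2 and
FRiP > 0.1 (both strict), organelle fraction within mean + 2 sd of the
library (one-sided high tail), capped at 16,000 cells by depth. The
companion z-score filters some pipelines apply require a score model that
is not part of this package; the absolute thresholds are authoritative
here.

## ACR calling

Each insertion is extended to a 150 bp interval centred on the site
(shift −75, extsize 150). Candidates are maximal runs where coverage
exceeds the Poisson(rate·150) upper quantile at `candidate_p = 1e−5`
(rate = global insertions per bp), runs closer than 150 bp merged, summit
= leftmost coverage argmax. This candidate heuristic is deliberately
simple — the decisive stage is the empirical permutation FDR: for each
candidate one width-matched interval (per permutation set; one set by
default, `n_perm_sets` configurable) is placed uniformly in
mappable ∖ exonic space, permutation intervals may overlap each other and
real peaks, and the threshold is the minimum Tn5 density t\* with
FDR(t) = #{perm ≥ t}/#{real ≥ t} < 0.05 scanning the observed densities.
Density is insertions per bp of peak span. Peaks >50% covered by
nucleosome calls or with mean overlapping fragment size >150 bp are
dropped; survivors become [summit−250, summit+250) windows (clipped and
flagged at chromosome ends). The atlas merge unions overlapping windows
across cell types and re-centres on the pooled-coverage summit; windows
that would still overlap after re-centring are shifted to enforce
disjointness, so every atlas ACR is exactly 500 bp.

## Gene activity and cell cycle

Gene accessibility counts insertions over the gene body plus a 500 bp
strand-aware upstream extension. Because every positive normalised value
is then set to 1 (zeros stay 0), the binarised matrix is identical for any
monotone positive normalisation; log counts-per-ten-thousand is used
internally before binarisation.

Marker genes use an exact conditional test on pseudobulk counts: given a
gene's total n across cell types, the focal count k is binomial(n,
lib_focal/lib_total) under the Poisson model; with shared negative-
binomial dispersion α (count-scale method of moments with library-size
offsets) the conditional becomes Pólya/beta-binomial with a = K·p₀/α,
b = K·(1−p₀)/α — exact at equal library sizes, recovering the binomial as
α→0. Two-sided mid-p; markers need BH FDR < 0.05 and log2FC > 0. Under a
Poisson null the p-values are uniform (KS-verified); under strong
overdispersion with unequal libraries the Pólya approximation is mildly
anti-conservative — a documented approximation, not a calibration claim.

Cell-cycle stages: per stage, the cell's score is the summed marker
accessibility; 1,000 permutations drawing equally sized sets from the
55-gene panel excluding the focal stage give the null mean/sd; z-scores
map to probabilities via the normal CDF and the argmax stage is assigned.
The 55-marker panel is dataset-specific, so a clearly labelled synthetic
stand-in ships as a replaceable TSV asset
(`assets/cell_cycle_markers.synthetic.tsv`).

## Cell-type specificity

Scores: CPM per cell type, p_c = CPM_c/ΣCPM, H = −Σ p_c ln p_c,
s_c = p_c·(1 − H/ln K). The literature this metric descends from does not
print the exact weighting; this standard form satisfies the qualitative
contract (1 for a point mass, 0 for uniform) and is flagged as a choice.

Bootstrap: per (ACR, cell type), B real replicates resample
`boot_cells = 250` cells with replacement from the focal type and
recompute s with the other types fixed at full-data CPM; null replicates
put a resample of 250 cells from the pooled mixed population in the focal
slot. p = (1 + #{null ≥ median(real)})/(1 + B). One subtlety: an ACR
whose signal sits entirely in the focal type scores exactly 1 in both
real and null replicates (the zero other-type profiles force a point
mass), so exact score ties are broken by focal CPM magnitude — the mixed
null's focal CPM is ~K-fold diluted, which resolves the tie in favour of
the real signal without affecting continuous cases. With B = 5,000 the p
floor 1/5,001 < 0.001 makes the significance cut attainable; the test
suite uses B = 1,000 (floor 1/1,001), which keeps the same property.
Labels: specific when significant in 1–2 cell types (leaf mode) or 1–3
(atlas mode), else broad.

## Candidate silencers, expression contrast, BMRs

Accessibility calls require all three: max per-base pileup coverage in
the ACR scaled per million insertions > 2 (per-million scaling makes the
threshold depth-independent; the source scale was unstated), raw count
≥ 20, and column-quantile-normalised CPM > 2. Breadth: broad at ≥ n−1
accessible cell types (n < 10) or ≥ n−2 (n ≥ 10); specific below 3 or 4;
else intermediate. H3K27me3 association means overlapping a domain or
lying within a 500 bp flank (one ACR width; "surrounding" is not
quantified upstream, so the flank is a parameter).

The expression contrast pairs genes linked to H3K27me3-broad ACRs
(ACR 500–5,000 bp upstream of the TSS, gene body >50% covered by
H3K27me3) with an equal-count control sample of genes near
H3K27me3-absent broad ACRs, rank-matched on overall expression, and
applies the one-tailed Wilcoxon signed-rank test per cell type (skipped
below 6 pairs).

BMRs are maximal runs of ≥3 consecutive 500 bp windows with methylation
strictly above the genome-wide mean (per context when given), with a
1e−12 float guard so an exactly-constant track yields none.

## Motif machinery

PWM scores are log2 likelihood ratios against a uniform (or supplied)
mononucleotide background. The score threshold for P < 1e−5 is computed
by dynamic programming over the discretized per-position scores; because
the DP support is bounded by 4^L, motifs ≤10 bp use an effectively exact
1e−9 grid and longer motifs 1e−4 (configurable). A consequence worth
knowing: at uniform background the best attainable tail probability is
≥ 4^−L, so motifs of ≤8 bp cannot reach P ≤ 1e−5 and produce no PWM hits
at that stringency — the six PRE classes are therefore shipped as IUPAC
pattern assets (CTCC `CTCCTCC`, CCG `CCGCCGCC`, G-box `CACGTG`, GA-repeat
`GAGAGAGA`, AC-rich `ACACACAC`, Telobox `AAACCCTA`) matched literally on
both strands; the exact definitions are replaceable inputs, not outputs,
of this package.

Control sets reproduce the target width multiset, placed uniformly in
mappable space minus exclusions, rejecting overlaps with the targets. The
binomial test is exact with p₀ = mean null capture (p₀ = 0 clamped up to
the null resolution; p₀ = 1 left alone, the upper tail is then exactly 1).
NB enrichment fits log μ = β₀ + β₁·1[type] + β₂·log(nonzero entries) on
412 cells per type (sampled with replacement and flagged when a type is
smaller), Poisson first, method-of-moments dispersion, one NB refit; BH
within cell type across motifs (a config-level choice; the alternative
global scope is a one-line change); enriched = q < 0.01 and β₁ > 0.05.
Family enrichment is the one-tailed hypergeometric upper tail.

## Synteny and conservation

Blocks violating the one-to-one rule (duplicate or overlapping intervals
on either side) are dropped pairwise; inverted blocks are reverse-
complemented so alignment runs in query orientation, and hit coordinates
lift back through the affine orientation transform.

The aligner mirrors short-sequence BLASTN parameterisation: exact 7-mer
seeds, an ungapped X-drop pre-filter (trigger 13, X-drop 8) so only
promising seeds reach the gapped stage, then affine Smith–Waterman
(match +1, mismatch −1, gap of length k costs 5 + 2k, i.e. first gap base
7) on a window around each seed cluster, with traceback for length and
identity. E = K·m·n·e^(−λS) with λ = ln 3 — the exact Karlin–Altschul
solution of ¼e^λ + ¾e^(−λ) = 1 for ±1 scoring on uniform background —
K = 0.62 (configurable; the E ≤ 1e−3 cut is validated by null
calibration, and ranking is K-independent), and raw sequence lengths for
m, n (no edge correction; sequences are short). Hits pass at E ≤ 1e−3
and length >20; the top 4 by score, non-overlapping, are kept. On random
sequence pairs the observed hits with E ≤ e stay within the expected ≤ e
per pair (checked at a factor-2 tolerance).

Classes: shared if any passing hit, lifted to partner coordinates,
overlaps an accessible partner ACR (the stricter direct-overlap reading);
variable if a hit exists without partner overlap; species-specific if no
hit; ACRs outside every block are reported as non-syntenic. Retention for
shared cell-type-specific ACRs: retained (same cell type), switched
(partner's type recorded), broadened, or unknown.

## Trajectory comparison

Motif deviations are chromVAR-style: observed motif-peak counts minus the
depth-scaled expectation over that expectation, z-scored against 50
background peak sets matched on accessibility decile. Neighbour-diffusion
imputation is deliberately omitted: the classification contract is
defined on kernel-interpolated curves (Gaussian kernel, bandwidth 0.1 of
the pseudotime range, 200 evenly spaced grid points, then per-motif
z-scaling; constant curves z-scale to zero).

DTW is boundary-anchored and monotone with absolute-difference local
cost; the distance divides the path cost by √G (G = features aligned
jointly, 1 per motif pair). Classification: k-means (k = 2) on the
distances, the higher-mean cluster accepted as the "high" group only when
its mean exceeds twice the low mean (guarding the all-conserved
degenerate case). Low-group motifs whose per-species linear trends share
sign are conserved. For everything else the shift is estimated by a
first-order Taylor regression: writing a(t) ≈ g(t + δ/2) and
b(t) ≈ g(t − δ/2), the difference Δ = a − b ≈ δ·g′(t), so regressing Δ on
the derivative of the mean curve estimates the pseudotime lead δ of
species A directly; the Wald p (BH-corrected across motifs, q > 0.05 →
unknown) gates the shift claim and sign(δ) names the leading species.
This replaces two alternatives that fail structurally: regressing Δ on
pseudotime has slope ≈ 0 whenever the transition sits mid-trajectory
(both curves are z-scaled to mean zero, so Δ is a centred bump), and the
DTW path lag's sign is corrupted by tie-breaking across the flat curve
segments; the raw lag is still reported descriptively. Grid-point
autocorrelation (from kernel smoothing) inflates the nominal Wald
significance — the gate orders motifs correctly but its p-values should
not be read as calibrated tail probabilities.

## Synthetic data: what it emulates, and not

The generators produce a uniform-background genome tiled into 14 kb slots
(one 2 kb gene each), 300 bp planted peaks in genic/proximal/distal
contexts (default ratio 19/52/29%), broad peaks active in all cell types
and specific peaks in one, plus nucleosomal decoy peaks whose insertions
carry fragment sizes >150 bp and which are covered by nucleosome calls —
so the fragment-size and nucleosome filters are exercised honestly. Depth
is negative binomial (default mean 2,000, dispersion 10); insertion
positions mix planted peaks (triangular around the midpoint, so summits
are well defined) with uniform background at a per-bp rate ratio `snr`
(default 5). H3K27me3 domains embed 40% of broad peaks (the silencer
truth, two PRE motif copies planted in sequence); methylation windows are
Beta(2,18) background with planted 5-window BMRs. The sister genome
copies blocks with i.i.d. substitutions (divergence 0.08–0.12 in the
study conditions), preserving a 60 bp core for shared/variable ACRs and
randomising species-specific ones; indels are deliberately not simulated
so the coordinate lift stays affine and the conservation truth exact.
Trajectories are sigmoid profiles with ±Δ pseudotime offsets and Gaussian
noise.

Not emulated: read-level sequencing error, barcode collisions/doublets,
non-uniform mappability, GC or Tn5 sequence bias, correlated peak
co-accessibility, genome rearrangements beyond whole-block inversion, and
realistic motif grammar. Passing tests therefore demonstrate correctness
of the statistics and algorithms under their stated models, not
robustness to every artefact of real libraries.

## Problem sizes

The reference study used throughout the tests and the acceptance script
is a 2 × 1 Mb genome, six cell types × 400 nuclei (~4.8 M insertions),
60 true peaks + 10 decoys; bootstrap B = 1,000 (p floor 1/1,001, same
attainability property as the production default 5,000); 10 seeds for the
conservation classes and 5 for trajectory recovery. These sizes make the
full pipeline run in about two minutes on one CPU while leaving every
planted signal unambiguous at the stated noise levels.
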