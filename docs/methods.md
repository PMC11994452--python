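# Methods

This note documents the statistical models, the synthetic world, the
numerical choices and the known limitations of `afmap`. Nothing here
states an empirical result that the test suite does not itself compute.

## Differential expression engine

Counts are modeled per gene as negative binomial with mean μ and
dispersion α (variance μ + αμ²), log link, and an offset of
log size factors. Size factors are DESeq-style median-of-ratios over the
genes positive in every sample; there is no pseudo-reference fallback, so
a dataset with no such gene raises. The design is intercept + condition
(AF = 1 vs SR = 0) + any numeric covariates (sex in the bulk cohorts,
sex + dataset dummy in the merged analysis); a rank-deficient design
raises and names the collinear columns.

Fitting is IRLS, vectorized across genes (the design is shared, so the
per-gene 2×2 or 3×3 normal equations are batched with `einsum`), 50
iterations maximum, convergence at a 1e-8 step, linear predictor clipped
to ±30 to avoid overflow. The Wald statistic uses the observed
information at the final weights, and p-values come from the normal —
standard GLM asymptotics, with calibration verified by null simulation
(rejection rate within [0.03, 0.07] at nominal 5%, n = 20 + 20, α = 0.2).

Dispersion is a per-gene method of moments on size-factor-normalized
counts, α̂ = max((s² − μ̄)/μ̄², 1e-8), with moments taken **within** the
condition groups and pooled with weights n_k − 1. The within-group form
matters: pooled-across-groups moments absorb a true condition effect into
the dispersion, which inflates the SE exactly for the genes one wants to
detect (measurably costing recall of planted effects). There is no
empirical-Bayes trend shrinkage and no log-fold-change shrinkage: the
reported log₂FC is the MLE. Both are deliberate simplifications relative
to full DESeq2; downstream thresholds (|log₂FC| > 0.25 etc.) therefore
operate on unshrunken estimates.

Genes with all counts zero are reported with missing statistics and
excluded from the BH denominator. "Concordant in both datasets" means
FDR < 0.05 separately in each cohort *and* matching fold-change sign; a
laxer reading (significant in one cohort, same sign in the other) is
available as `mode="either"` in `concordant_degs`.

## Specificity AUC

One-vs-rest Wilcoxon rank-sum with midranks; AUC = U/(n₁n₂) so ties
count one half, making it identical to exhaustive pairwise comparison
(tested against that oracle). P-values use the normal approximation with
tie-corrected variance and no continuity correction; a constant feature
returns AUC 0.5, p 1. FDR is computed across features within each group
contrast, not pooled across groups, mirroring per-cell-type marker
testing. The signature filter applies the rank-sum test two-sided; since
it is combined with AUC > 0.5 the choice is nearly immaterial, and it is
configurable.

## Module (signature) score

All genes are binned into 24 equal-frequency bins of mean expression
(quantile bins avoid empty bins on skewed means; tied means share a
bin). For each signature gene, 100 control genes are drawn with
replacement from its bin, excluding the gene itself when the bin offers
alternatives; the score per cell is mean(signature) − mean(pooled
controls). 24 bins / 100 controls are the defaults of the widely used
single-cell implementation of this score; the scoring is deterministic
given the seed.

## Meta-cells

Within each donor × cell-type group (groups smaller than k are skipped
with a warning), a k-NN graph (Euclidean, k = 30, self included) is built
in a 10-component PCA embedding of the log-normalized RNA; seeds are
visited in seeded-random order and a neighborhood is emitted iff it
shares at most 10 nuclei with every meta-cell already emitted in the
group. All eligible seeds are tried (no target count — deterministic and
parameter-free), and the resulting assignment is applied unchanged to
the peak matrix, so both modalities aggregate identically. The original
meta-cell tool does not document its seed-selection or
overlap-enforcement order; this greedy procedure satisfies the same
constraints but need not reproduce the original meta-cell count. The
embedding is plain PCA — batch correction of the embedding is out of
scope, and the synthetic multiome has no batch structure.

PCA standardizes features (constant features pass through unscaled) and
uses a deterministic solver, so repeated runs agree bitwise.

## Motif deviations

For motif m and nucleus i, X_im is the summed accessibility of the
motif's peaks, E_im = f_i · Σ w_p its expectation from the nucleus total
f_i and peak weights w_p = peak total / grand total, and
raw_im = (X − E)/E. Each motif peak is paired with 50 background peaks
drawn with replacement from its joint bias bin — a 10 × 10 quantile grid
over z-scored GC content and log1p mean accessibility (the grid replaces
chromVAR's Mahalanobis-nearest sampling; simpler, same intent). The b-th
background set yields dev_b by the same formula; the reported z is
(raw − mean_b)/sd_b. Motifs with zero background spread get missing z.
A motif containing every peak has raw deviation identically zero (exact
test). Mean accessibility is computed from exact integer column sums so
that identical peaks are exact ties — this also makes z-scores exactly
invariant under global count scaling (doubling all counts changes
nothing but the log1p covariate, which is rank-preserving).

## Footprints

Insertion positions (one per fragment row) are histogrammed by offset
from each motif-site midpoint (minus-strand sites flipped), summed over
sites and group members, and divided by the group's mean count at
offsets 200–250 bp, so an uninformative profile sits at 1. No Tn5
sequence-bias correction is applied — a divergence from reference
footprinting tools that matters on real sequence but not on the
synthetic fragments.

## Peak annotation

Interval semantics are 0-based half-open throughout; touching intervals
do not overlap. A peak's cCRE class is the overlapping class with the
greatest overlap length, ties broken prom > enhP > enhD > K4m3 > CTCF;
no overlap gives `not.Encode`. A unified peak counts as "called in" a
cell type if any of that cell type's called peaks overlaps it
(any-overlap, not identity), and "cell-type specific" means called in
exactly one. Atlas matching reports |peaks overlapping atlas set| /
|peaks|; pairs strictly below the 25% threshold are dropped from the
filtered output (a fraction of exactly 0.25 is kept), the full matrix is
retained. Strand is ignored for all peak overlaps.

## Coexpression modules

Genes pass the merged-cohort DE prefilter (base mean > 1 strictly,
|log₂FC| > 0.05, nominal p < 0.05). Expression is ln(1 + CPM) — an
approximation of the variance-stabilizing transform used by reference
workflows — and sex/dataset are removed per gene by least squares on
centered covariates, which preserves each gene's grand mean. Adjacency
is ((1 + r)/2)^9 (signed network, Pearson r), TOM follows
(L_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with sums excluding i and j,
and clustering is average linkage on 1 − TOM.

The reference dynamic tree cut is replaced by a **static cut at 0.8 of
the merge-height range** (h_min + 0.8·(h_max − h_min)). This default was
chosen after evaluating three static rules on four scenarios — clean
planted blocks, undersized blocks, near-duplicate blocks, and the full
pipeline's filtered gene set: the fraction-of-range rule at 0.8 was the
only one correct on all four. A cut at the largest inter-merge gap fails
when within-module merges grade smoothly into the background, and a cut
chosen to maximize the number of clusters above `minModuleSize` actively
absorbs background genes to push undersized blocks over the threshold.
Clusters below 50 genes become label 0 (unassigned); modules whose
eigengenes (first PC of standardized module expression, sign-oriented to
correlate positively with the module mean profile) exceed correlation
0.75 are merged pairwise, highest first, to a fixed point. The kME-based
membership reassignment step of the reference implementation is omitted.
Correctness is defined by planted-module recovery (ARI ≥ 0.9), not by
equivalence to the reference tool.

## The synthetic world

Defaults emulate the study design at desk scale, fixed before the
recovery tests were run (two corrections made during development are
recorded in the project ledger):

- **Multiome**: 4 donors per condition (the study recruited 4 + 4; one
  AF sample failed QC), 400 nuclei per donor, 8 cell types with CM 25%
  and FB 23% of nuclei, 2,000 genes, 3,000 peaks, 20 motifs with 30
  peaks each. Counts are NB with α = 0.2 and log-normal(0, 0.3) library
  sizes. Markers get a 3× mean uplift in their cell type; the AF program
  (30 up + 30 down genes) gets a 3× CM baseline uplift plus a 2× up- (or
  down-) shift in AF CM nuclei. Planted marker/program genes have their
  base mean floored at the gene-universe median — marker lists in real
  data are by construction well-detected genes.
- **Bulk**: two cohorts of 40 AF + 40 SR samples (desk-scale stand-ins
  for the 161 + 81 originals), gene base means ~100× the single-nucleus
  scale (median ≈ 50 counts, typical of filtered bulk RNA-seq), shared
  DEGs at log₂FC 1.0 / 0.8 (the AF program plus 20 extras), 20
  cohort-private DEGs each, 50 sex-linked genes (+1 log₂ in males), 100
  cohort-2 batch genes, and one antisense pair whose "unstranded"
  matrix reports the pair sum for both genes. Three 60-gene modules
  share a latent factor (loading 0.7 on the natural-log scale) whose
  mean shifts by ±1 between conditions — giving within-module
  correlation ≈ 0.6–0.7 and condition-linked module eigengenes, as
  module analyses of disease cohorts typically show.
- **Fragments**: uniform background (100 insertions per nucleus across
  the synthetic chromosome); CM nuclei add Poisson site-directed
  insertions within ±150 bp of each driver-motif site, excluding the
  protected ±10 bp core, at 2 per site (SR) and 2× that in AF. The
  enriched region is kept inside the normalization flanks (200–250 bp)
  so flank normalization does not cancel the group contrast.

The generator does **not** emulate: doublets and ambient RNA, batch
effects in the multiome, realistic genome structure (one synthetic
chromosome, uniformly tiled non-overlapping peaks), sequence content
(GC is drawn Beta(5,5) per peak, independent of any sequence), motif
match scores, or read-level noise. A green recovery test therefore
establishes that the pipeline's logic recovers effects of the stated
size under NB sampling noise — not that it is robust to the artifacts
real QC pipelines exist to remove.

Determinism: every generator derives its streams from
`SeedSequence([seed, stream])`, so outputs are bit-identical for a given
config and seed, and different seeds change values but never shapes.

## Scaled-down test configurations

The multi-seed end-to-end checks (driver-TF recovery and the null
driver check, and the pipeline determinism check) run a smaller world —
120 nuclei per donor, 700 genes, 800 peaks, 10 motifs, 20 + 20 bulk
samples — with meta-cell k = 10 / max overlap 3, scaled with the group
sizes so each donor still contributes several meta-cells. This keeps the
whole suite within its runtime budget; single-seed checks (meta-cell
contract, motif calibration, signature recovery, concordance) run at the
default scale.

## Known limitations

- Moments dispersion is noisy at small n; with 4 donors per condition
  the pseudobulk tests are conservative for weak effects.
- The Wald-normal p is anti-conservative for very low counts; the
  calibration band is verified at base means ≥ ~5.
- Median-of-ratios assumes mostly-null, roughly balanced DE; strongly
  unbalanced planted fractions bias fold-change estimates (visible in
  the engine's own tests).
- The static tree cut has no concept of nested module structure; deeply
  nested modules would require the dynamic cut it replaces.
- Driver-TF selection is correlational across meta-cells; it does not
  model TF abundance–activity relationships and cannot separate
  co-binding TF families (motif similarity is not modeled at all).
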