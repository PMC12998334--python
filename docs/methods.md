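# Methods

This note documents the models implemented in `periprog`, the defaults that
matter, what the synthetic generators do and do not emulate, and the design
decisions taken where the underlying procedures are conventionally
under-specified.

## RNA preprocessing

Cells are filtered on three criteria: detected genes within [500, 6000]
(boundaries kept), and mitochondrial fraction strictly below 10%
(a fraction of exactly 10% removes the cell). Mitochondrial genes are
recognized by a configurable id prefix (default `MT-`), since probe naming
conventions differ between assays. Counts are normalized per cell to a
scale factor of 10,000 and transformed with the natural log of 1 + x, so a
cell's back-transformed values sum exactly to the scale factor.

**Highly variable genes.** Ranking follows the vst idea — variance of
clipped standardized values under a mean–variance trend — computed on the
back-transformed (depth-normalized count) scale. The trend is a unit-slope
line in log10 variance versus log10 mean with a trimmed-median intercept.
On this scale Poisson noise gives variance proportional to the mean, so
unit slope is the theoretically consistent null trend; a freely fitted
polynomial can pass *through* a band of genuinely variable genes whenever
they concentrate in one mean range (which planted programs do at desk
scale) and thereby erase exactly the signal the step must find. Clipping is
at sqrt(n_cells); ties in the ranking break lexicographically by gene id.

**PCA and clustering.** PCA operates on per-gene centered, unit-scaled
values; the sign of each component is fixed by making its
largest-magnitude loading positive, so embeddings are bitwise
reproducible. Clustering builds a k = 20 nearest-neighbor graph (the
neighborhood includes the cell itself), weights edges by the Jaccard index
of neighborhoods pruned below 1/15, and optimizes modularity with seeded
Leiden at the requested resolution (0.2 for cohort-wide, 0.6 for
per-sample analyses by default). Leiden was chosen over a hand-rolled
greedy Louvain because it is the installed, field-standard optimizer of the
same objective and is deterministic under a seed. Cluster ids are relabeled
by decreasing size.

## Marker genes

For each cluster versus the rest: log2FC = log2((mean_in + 1) /
(mean_out + 1)) over back-transformed expression; only positive fold
changes above 0.25 are tested (two-sided Wilcoxon rank-sum); BH adjustment
runs over the tests actually performed, matching the behavior of the usual
wrapper of adjusting within the emitted table. The rank test is exact
whenever both groups have ≤ 25 cells (midranks for ties) and otherwise uses
the tie-corrected normal approximation with continuity correction.
Cluster-specific genes require strictly log2FC > 1 **and** adjusted
P < 0.01. No min.pct filter is applied; expressing fractions are reported
instead.

## Consensus NMF and recurrent programs

The NMF input is the HVG-restricted normalized matrix with each gene row
scaled to unit variance (no centering, preserving nonnegativity).
Factorization uses multiplicative updates for squared Frobenius error from
seeded uniform-random initialization; the recorded relative-error sequence
is non-increasing and iteration stops at a relative change below 1e-6.

Consensus over restarts: spectra from all restarts are L2-normalized and
pooled; a component is discarded when its mean cosine distance to its
floor(R/2) nearest pooled neighbors exceeds 0.5 (outlier local optima);
survivors are grouped by seeded k-means into k groups; the consensus
spectrum is the per-gene median of each group, renormalized; usages are
refit by nonnegative least squares. Program order is deterministic.

**Rank selection** over k = 4…9 computes, per k, the mean cosine
silhouette of the pooled-component grouping (stability) and the relative
Frobenius error of the consensus fit. The chosen k maximizes
stability − error, with ties to the smaller k. Stability alone is not
sufficient: merging two true programs at k one below the truth is often
perfectly reproducible across restarts, so pure argmax-stability
systematically under-selects; subtracting the reconstruction error encodes
what an analyst inspecting both curves does, while leaving the pure-noise
case (flat stability, slowly declining error) at the smallest k.

**Consolidation.** Each program contributes its top-weight gene signature
(ties by gene id). At cohort scale the signature length should be a small
multiple of the expected program size; the synthetic default is 30 genes
(planted programs load 25 genes of 500), the analysis of a real 2,000-HVG
matrix would use the conventional 200. Signatures are clustered by
average linkage on 1 − Jaccard and the tree is cut at a configurable
number of RPs (default for synthetic tests: shared + private planted
count). A gene belongs to an RP when it appears in at least one-third of
the member signatures, boundary inclusive (1 of 3 members qualifies; 1 of
4 does not). Overlap against reference program sets uses the
hypergeometric upper tail with a configurable universe (default: all genes
in the matrix) and BH adjustment across the batch.

## ATAC scoring

Fragments are 0-based half-open and assumed pre-shifted; each fragment
contributes Tn5 insertions at `start` and `end − 1`, weighted by its
duplicate count, so a fragment inside one peak adds 2.

**TSS enrichment** is the per-barcode insertion density within ±50 bp of
the nearest TSS divided by the density in the 1,901–2,000 bp flanks, with
the flank count floored at 0.1 to keep the ratio defined (capped at 100).
QC keeps barcodes with enrichment ≥ 4 and ≥ 1,500 distinct fragments.

**LSI** is a single-pass TF-IDF (term frequency per cell ×
log(1 + n_cells/df)), log-scaled, followed by truncated SVD; the leading
component is dropped when it correlates with log depth above 0.9. The
iterative re-clustering of the full procedure is intentionally omitted —
single-pass LSI is deterministic and adequate at the scales this package
targets.

**Gene activity**: insertions inside the strand-oriented window
[TSS − 2,000, gene end] weigh 1; beyond the window the weight decays as
exp(−d/5,000) out to 100 kb. Scores are depth-normalized to 10,000 per
cell and log1p-transformed, mirroring the RNA normalization so module
scores are comparable across arms.

**chromVAR deviations**: for motif m and cell c, raw = (X − E)/E with
E = (cell total) × (all-cell fraction of insertions in m's peaks); the
z-score standardizes raw against the same statistic over each of 50
background draws, where every peak draws from its 250 nearest neighbors in
standardized (GC, log1p mean accessibility) space, with replacement and
self allowed. Identities that follow from the construction — raw ≡ 0 when
a motif covers all peaks or when only one cell is present, and
Σ_c X = Σ_c E per motif — are enforced by tests. Deviations are computed
jointly over all cells; a per-sample mode is a caller-side subset.

## Module scores and regulator ranking

Module scores follow the bin-matched control-gene scheme: genes are placed
into 24 equal-size bins by mean value; each target gene draws 100 control
genes with replacement from its bin (targets excluded; if a bin holds only
targets the pool falls back to all non-target genes, with a warning); the
score is the mean target value minus the mean control value per cell.
Optional smoothing replaces each cell's value with the mean over its k
nearest embedding neighbors (k = 15 when enabled; off by default) — a
deterministic stand-in for diffusion-based imputation that preserves the
smoothing intent without the extra model. Pearson correlations between
module scores and all motif z-scores are computed per cell over barcodes
shared by both matrices; constant vectors give missing entries, which are
excluded from ranking and imputed as 0 only for profile clustering
(average linkage on correlation distance). Regulator ranking sorts motifs
by descending r, ties by motif id.

## Cohort statistics

Fisher's exact test uses the probability-mass two-sided criterion (sum of
fixed-margin tables with probability ≤ observed, relative tolerance 1e-7)
and reports the sample odds ratio ad/bc with explicit ∞/NaN conventions.
The Mann–Whitney dispatch is exact when both groups have ≤ 25 values and
the pooled data are tie-free, otherwise a tie-corrected normal
approximation with continuity correction 0.5 — the convention of the
common clinical statistics environments, pinned by the worked cohort
examples in the tests. Kruskal–Wallis applies the tie correction, with
pairwise Mann–Whitney post hocs Holm-adjusted. The migration ratio sums
Euclidean step lengths of 2-D centroid tracks within the 0–24 h and
72–96 h windows; a zero early-window distance yields a missing ratio.

## Synthetic data: what it emulates, and what it does not

`make_program_cohort` draws, per sample, per-cell program usages from a
symmetric Dirichlet (α = 0.3; α = 0 means one-hot) over that sample's
programs (3 shared across samples + 1 private by default), and Poisson
counts with expectation library size × (usage · spectra) plus a
noise_level = 0.1 background (log-normal library sizes around 2,000;
mitochondrial ids carry extra background weight so QC is exercisable).
Program spectra load disjoint 25-gene blocks (5% of 500 genes) with gamma
weights. Defaults — 3 samples × 300 cells × 500 genes — were chosen as the
smallest configuration in which rank selection over the full 4–9 range,
consolidation, and marker recovery are all non-trivially exercised.

`make_multiome_pair` gives every gene a promoter peak on a synthetic
chromosome (5 kb gene spacing, 500 bp peaks, 1,000 peaks total) and lets
the accessibility rate of peaks carrying the planted TF's motif be
multiplied by (1 + tf_coupling × program-1 usage). With coupling > 0 the
planted motif additionally covers the promoter peaks of program 1's genes
(its regulon), coupling both the motif deviations and the gene-activity
module score to the planted usage; at coupling 0 the planted motif is a
plain density-sampled motif, exchangeable with every other one — the
correct null for regulator-recovery false-positive checks, since a motif
hard-wired onto the module's own promoters shares sampling noise with the
module score even without any regulatory signal. Peak GC is uniform on
[0.3, 0.7]; per-cell fragment depth is log-normal around 3,000 and
fragments lie wholly inside peaks.

Deliberately not emulated: doublets, batch effects, ambient RNA,
zero-inflation beyond Poisson, realistic genome architecture (introns,
overlapping genes, distal enhancers), motif PWM scanning, and
fragment-length periodicity. Passing tests therefore demonstrate that the
algorithms recover planted structure under their own model assumptions at
desk scale — not performance on real tissue data.

## Known limitations

* NNLS usage refitting loops over cells; it is exact but not tuned for
  cohorts beyond ~10^4 cells.
* The Jaccard consolidation treats signatures as unordered sets; weighted
  overlap variants are not implemented.
* The number of RPs is a caller-chosen tree cut, as in the underlying
  procedure; no gap statistic is applied.
* Deviations build a dense peak × cell array internally; peak sets beyond
  ~10^5 peaks would need a sparse background path.
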