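# Methods

`eecatlas` re-implements, as a tested library plus narrative analysis
scripts, the computational workflow behind a region-resolved single-cell
atlas of murine enteroendocrine cells (EECs): hormone-secreting epithelial
cells of the stomach, upper and lower small intestine (USI/LSI), caecum and
large intestine (LI), classically named by their dominant hormone (D = Sst,
G = Gast, I = Cck, K = Gip, L = Gcg/Pyy, N = Nts, S = Sct, X = Ghrl,
EC = Tph1, ECL = Hdc, plus an Insl5-defined population).  Every stage runs
on synthetic data with planted ground truth, so the claims the tests make
are about the algorithms, not about any particular sequencing run.

## Quality control

Counts arrive as 10x-style MTX triples or AnnData, with a per-cell region
label.  Filters run per region, genes first, then cells, once and without
iteration:

* gene kept iff detected (count > 0) in **≥ 3 cells** (inclusive) *and*
  total raw counts across the region **≥ 500** (USI, LSI) or **≥ 1000**
  (stomach, caecum, LI);
* cell kept iff its mitochondrial read fraction (case-insensitive `mt-`
  symbol prefix; the mito gene list itself is a package choice) is
  **strictly below 20%** (USI, LSI, LI) or **25%** (stomach, caecum).

Boundary semantics follow the rules' wording literally: "at least" is
inclusive, "less than" is exclusive.  Filtering is idempotent.

## Normalization

The working scales are CPM (count / cell total × 10⁶), log2(CPM + 1), and a
per-gene z-scaling ahead of PCA.  The upstream ecosystem's regularized-NB
normalization is deliberately not re-implemented; its stated intent —
removing the %mito covariate — is preserved by an ordinary-least-squares
residualization of log2(CPM+1) per gene (covariate centred, intercept
retained, so gene means are unchanged and residuals are exactly orthogonal
to %mito).  Variable genes are ranked by standardized variance of
log2(CPM+1): gene variance divided by the median variance of its
mean-expression decile (a 10-bin running-median mean–variance trend).  The
criterion is a package decision; no particular method was mandated.  Note
that the trend normalization is relative — in a matrix whose high-abundance
bins are mostly structured genes, the trend absorbs the structure — which
is the expected behaviour of trend-standardized scores.

## Hormone positivity: Huang fuzzy thresholding

For each panel hormone (default Gcg, Cck, Sct, Pyy, Nts, Insl5, Sst, Ghrl,
Gip, Gast, Ppy, Tph1, Hdc) a threshold is computed on the per-gene CPM
distribution over **all regions combined**; Sst and Ghrl are additionally
thresholded within the stomach only, where their ambient expression is
high, and stomach cells are judged against the stomach-scoped cut.  The
threshold is Huang's fuzzy-entropy minimizer ("Huang2"): values are binned
into 256 equal-width bins over [min, max]; for a candidate cut t with class
means μ₀ (bins ≤ t) and μ₁ (bins > t), each bin value x has membership
u = 1 / (1 + |x − μ_class| / C) with C the data range, and the chosen cut
minimizes Σ h(bin)·S(u), S(u) = −u ln u − (1−u) ln(1−u).  Ties break to the
lowest cut; the result is the upper edge of the winning bin, on the CPM
scale.  The zero bin is kept in the histogram — hormone genes are zero in
most cells and the threshold must sit above that mass.  A cell is positive
iff CPM **strictly greater than** the applicable threshold.

One wording conflict is resolved deliberately: positivity is compared on
the CPM scale (threshold and value alike), because thresholds are defined
on CPM distributions; comparing a raw count to a CPM threshold would mix
scales.  The alternative reading (raw-count comparison) is not implemented.
Likewise "per region" is read as *the exception genes only*: all other
genes get one combined threshold, which is the only reading consistent with
computing thresholds "after combining cell data from all regions".

Co-expression summaries report, per ordered hormone pair (X, Y), the number
of X-positive cells, the fraction of them Y-positive, the dot-plot colour
statistic log2(mean CPM of Y over X-positive cells + 1), and a "none"
fraction (X-positive cells positive for no other panel hormone).  Venn
counts enumerate all 2^k − 1 membership combinations for up to four
hormones and reconcile exactly with positivity column sums.

## Clustering, annotation and differential expression

Per region: scale → exact PCA (region-specific depth: 8 stomach, 11 USI,
20 LSI, 10 caecum, 11 LI; component signs fixed so the largest-magnitude
loading is positive) → tSNE for display (scikit-learn backend, perplexity
30, auto-reduced for small cohorts; clustering never runs on tSNE
coordinates) → k-means on the PC scores with k = 10 (k-means++ init, best
of 10 restarts).  The source workflow mentions both k-means and a
"resolution" parameter; k-means with k = 10 is implemented per the literal
text and `resolution` is accepted and ignored with a warning.  Clusters are
annotated by the marker (Sst→D, Gast→G, Cck→I, Gip→K, Gcg→L, Nts→N, Sct→S,
Ghrl→X, Tph1→EC, Hdc→ECL, Insl5→Insl5) with the highest z-scored mean
expression across clusters, if that z-score reaches 1.0; clusters dominated
by non-EEC markers (Mki67, Alpi) become "non-EEC" and are excluded from
EEC-only analyses; the rest stay "unassigned".

Differential expression is one-vs-rest negative-binomial regression on raw
counts: per eligible gene (detected in ≥ 25% of in-cluster cells,
min.pct = 0.25), the model count ~ intercept + in-cluster indicator with a
log total-count offset is fit twice (with/without the indicator) at a fixed
per-gene dispersion estimated by method of moments from group-wise rate
fits (floored at 1e-3); the p-value is a 1-df likelihood-ratio test.
Bonferroni correction runs over the tested genes (no correction method was
mandated; Bonferroni matches the upstream ecosystem's default), and by
default only positively enriched genes are reported.  log2 fold change is
computed on mean CPM with pseudocount 1.  "Top markers" filters
p_adj < 0.05 and log2FC > 1.5 and ranks by log2FC (the source describes a
multi-criterion ordering without a formula; fold-change ranking is the
implemented default).  Non-converging fits are flagged with p = 1.

## GPCR cell-signalling subspace

A curated mouse gene list (~140 symbols, packaged, versioned, overridable)
covers GPCRs, G-protein subunits and regulators, GPCR kinases, adenylate
cyclases, phosphodiesterases, β-arrestins, PLC and PKA/PKC isoforms, AKAPs,
ion channels, calcium-release mediators and ryanodine receptors.  The
original study's exact list is in its supporting information and is not
reproduced; the packaged list is this package's own curation of the quoted
categories.  The subspace pipeline is the full pipeline restricted to the
list (restrict → scale → PCA(10) → tSNE → k-means); with the gene set equal
to all genes and equal seeds, its output is bit-identical to the full
pipeline.  Subspace DE delegates to the NB machinery on the gene-set
columns while keeping full-transcriptome library sizes as offsets.

## CCA integration (simplified)

Integration features are the union of per-dataset variable genes, ranked by
summed standardized-variance rank, truncated to 2000 and intersected with
the genes present everywhere.  For two scaled matrices X₁, X₂ on shared
features the cross-product K = X₁X₂ᵀ is SVD-truncated to n_cc (default 20;
no component count was specified upstream); L2-normalized rows of U and V
embed both datasets in one canonical space, and singular values normalized
by the largest are reported as canonical correlations.  More than two
datasets merge pairwise onto the largest in decreasing-size order, each
merge re-decomposing the grown reference against the next dataset, so the
final space covers every cell.  The published anchor-finding, anchor
weighting and expression-correction stages are out of scope by design: the
implemented contract is the CCA joint embedding itself.  No corrected
expression matrix is produced.

## Calcium responder statistic

Traces are background-subtracted fura-2 340/380 ratios sampled every 2 s
with declared half-open stimulus windows [start, end) in sample indices.
For each stimulus: m = argmax of the ratio inside the window (ties →
earliest).  If m is within 5 samples of onset, the response window is the
first 10 samples of the stimulus; otherwise it is [m−5, m+5) ("centred"
with an even window is resolved as 5 before, 5 at-and-after the max),
shifted left if centring would run past the window end.  The baseline is
the 10 samples immediately before onset.  R and R0 are the two means,
fold = R/R0 (invariant to positive rescaling of the trace); significance is
an unpaired equal-variance two-sided Student's t-test between the two
10-sample sets, and a cell is a responder iff p < 0.01 **and** R > R0 (the
direction requirement substitutes for a one-tailed test).  Degenerate
zero-variance windows: equal means → p = 1; separated means → treated as
the p → 0 limit.  Cohort summaries optionally gate on a positive-control
stimulus (e.g. 70 mM KCl), report responder Venn overlaps across test
stimuli, and add the per-stimulus one-sample one-tailed t-test of fold
changes against 1.  Because the response window is selected at the
in-window maximum, the null responder rate exceeds the nominal α — a
documented anti-conservativeness of the procedure, exercised by a test.

## Synthetic data generator

Counts: NB(mean, size) with mean = libsize × CPM/10⁶ × region shift.
Per-type CPM programs define hormones ("on" in the planted type, ambient
2 CPM elsewhere, overridable per (gene, region) — the default atlas plants
60 CPM ambient Sst/Ghrl in the stomach), signalling-gene programs, and
ten strong marker-program genes per type at 1000 CPM (real EEC subtypes
carry on the order of ten distinctive genes beyond their hormone; with
fewer, per-region PCA has too little signal at realistic cohort sizes).
Background gene CPMs are rescaled per type so expected total CPM is 10⁶,
making the log-normal library-size draw (median 10⁴, σ_log 0.5) the
expected total count.  Mito genes (five `mt-` symbols) are calibrated per
cell so the expected mito fraction equals a Beta(2, 25) draw (mean ≈ 7.4%).
The shared NB size defaults to 10 — typical of abundantly expressed genes
in UMI data, and required for the positivity-recovery guarantee (≥ 95%
balanced accuracy at ≥ 8× mode separation) to be satisfiable at all: at
size ≈ 2 the on-state coefficient of variation (~0.7) puts ~10% of truly-on
cells below any between-modes cut regardless of separation.  Dispersion is
a spec field, so noisier regimes remain one assignment away.  Not
simulated: ambient RNA, doublets, UMI saturation, gene–gene correlation
beyond the program structure — so passing tests certify the algorithms
under the stated model, not robustness to those artefacts.

Traces: baseline + Gaussian noise; planted responders add a transient with
a linear 5-sample rise to the drawn amplitude and exponential decay
(τ = 10 samples).  A degenerate zero amplitude corrects the truth entry to
non-responder.  Stimulus windows must be non-overlapping, inside the trace,
and preceded by ≥ 10 samples.

## Problem sizes and numerical choices

The bundled analyses and acceptance measurements run at: 5000 cells
(5 regions × 7 types) for positivity/co-expression, 2000 cells for
clustering recovery, 2000 genes for DE null calibration and 300 genes ×
2000 cells for DE power, 600 cells for the subspace checks, 300-cell
duplicated/batch-shifted cohorts for integration, and 200-cell trace
cohorts — sizes chosen so each stage's statistical question is answerable
while a full pass stays interactive.  Determinism is enforced throughout:
generators take explicit seeds, PCA/SVD fix component signs
(largest-|loading| positive), k-means uses a fixed random_state, argmax
ties break to the earliest index, and Huang ties break to the lowest cut.
tSNE determinism is backend-version-specific and tSNE output is therefore
excluded from the bitwise end-to-end reproducibility contract (cluster
labels come from PC scores, not tSNE).

## Known limitations

* The NB dispersion is shared across genes; no gene-wise trend.
* The CCA merge order (largest-first onto a growing reference) is a
  package decision; no order was specified upstream.
* Whether the subspace embedding should consume integrated or per-region
  normalized values is left to the caller (both are accepted); the bundled
  analysis uses the combined-atlas log-CPM.
* The positivity raw-count-vs-CPM wording conflict is resolved to CPM (see
  above); users wanting the other reading must threshold counts themselves.
* Real-data accession paths (public count matrices for the optional
  integration of published datasets) are supported only as ordinary MTX
  inputs; no downloading or re-analysis is bundled.
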