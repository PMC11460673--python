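# eecatlas

Analysis toolkit for region-resolved single-cell transcriptomics of murine
**enteroendocrine cells (EECs)** — the hormone-secreting epithelial cells of
the gut (~1% of the epithelium), named by their dominant hormone (D = Sst,
I = Cck, K = Gip, L = Gcg/Pyy, N = Nts, S = Sct, X = Ghrl, EC = Tph1,
ECL = Hdc).  It is written for people who have region-labelled 10x-style
count matrices (stomach, upper/lower small intestine, caecum, large
intestine) plus fura-2 calcium-imaging traces, and want the whole chain
from raw counts to "which cells make which hormones, which receptors define
them, and which cells respond to which stimulus" as tested, reproducible
code.

The pipeline:

1. **QC** — per-region gene filters (detected in ≥ 3 cells; total counts
   ≥ 500 in USI/LSI or ≥ 1000 elsewhere) and strict %mito cell cut-offs
   (< 20% USI/LSI/LI, < 25% stomach/caecum).
2. **Normalization** — CPM, log₂(CPM+1), OLS residualization of %mito,
   per-gene scaling, trend-standardized variable-gene selection.
3. **Hormone positivity** — per-gene **Huang fuzzy-entropy thresholds** on
   the CPM distribution over all regions combined (Sst/Ghrl additionally
   thresholded inside the stomach): the 256-bin cut minimizing
   Σ h(x)·S(u(x)), with membership u = 1/(1 + |x − μ_class|/C) and
   S(u) = −u ln u − (1−u) ln(1−u).  A cell is positive iff CPM > threshold.
   Co-expression dot-plot tables and ≤ 4-hormone Venn counts follow.
4. **Clustering/annotation/DE** — scaled log-CPM → PCA (8–20 PCs by
   region) → tSNE → k-means (k = 10) → marker-based EEC naming →
   one-vs-rest **negative-binomial regression** DE (log library-size
   offset, method-of-moments dispersion, likelihood-ratio test, Bonferroni,
   min.pct = 0.25, positively enriched genes only).
5. **GPCR signalling space** — the same embedding restricted to a curated
   list of receptor/signalling genes (packaged, overridable).
6. **Integration** — simplified CCA: SVD of the cross-product of scaled
   expression over 2000 shared integration features, giving one canonical
   embedding for all regions.
7. **Calcium responders** — fura-2 R/R0 fold change over a 10-sample
   window centred at the in-window maximum (first-10 rule near onset),
   Student's t-test vs the 10 pre-onset samples, p < 0.01 and an increase
   required; positive-control gating and response Venn summaries.

A first-class synthetic-data generator (`eecatlas.synthetic_data`) draws
multi-region NB count matrices with planted cell types, bimodal hormone
programs, %mito and library-size variation and batch shifts, plus fura-2
trace cohorts with planted responders — so every stage is testable against
known truth without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole story on the default
5000-cell synthetic atlas and a 200-cell trace cohort, writing tidy tables
under `results/`.  For example:

```bash
python analysis/03_hormone_positivity.py
```

prints (abridged):

```
gene    scope  threshold  n_cells
 Gcg combined 226.378971     5000
 Sst combined 449.467060     5000
 Sst  stomach 561.833826     1000
Ghrl combined 440.313576     5000
Ghrl  stomach 799.245955     1000

balanced accuracy vs planted truth:
Sst     0.9968
Gcg     1.0000
Ghrl    0.9992

USI Venn counts (Gcg/Cck/Sct/Pyy):
   USI         Cck       1    125
   USI         Sct       1    125
   USI     Gcg+Pyy       2    249
```

Read: thresholds sit between the ambient and "on" CPM modes (the
stomach-scoped Sst/Ghrl cuts are higher because gastric ambient expression
is high); positivity calls recover the planted truth at ≥ 99.7% balanced
accuracy; and the USI Venn table recovers the planted co-expression
structure — 125 pure Cck⁺ (I) and Sct⁺ (S) cells and 249 of the 250
Gcg⁺Pyy⁺ L-cells, with a single spurious triple.  Similarly,
`analysis/04_cluster_de.py` reports per-region cluster-vs-truth ARI of
0.989–1.000 with every planted type correctly annotated, and
`analysis/07_calcium_responders.py` classifies the trace cohort at ~0.97
balanced accuracy with a KCl-gated responder Venn.

## Layout

```
src/eecatlas/        library: io_formats, qc, normalize, hormone_threshold,
                     cluster_annotate, subspace, integrate, calcium,
                     synthetic_data, pipeline (+ packaged signalling gene set)
analysis/01..07      narrative drivers writing results/ tables
tests/               pytest suite with independent brute-force oracles
docs/methods.md      model, assumptions, parameter choices, limitations
```
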