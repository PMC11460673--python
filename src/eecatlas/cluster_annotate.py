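"""Per-region embedding, clustering, annotation and NB differential expression.

The per-region pipeline scales the normalized expression, runs exact PCA
(the number of PCs is a per-region choice: 8 stomach, 11 USI, 20 LSI, 10
caecum, 11 LI), embeds with tSNE for display, clusters the PC scores with
k-means (k = 10), names clusters by their dominant hormone marker using the
standard EEC nomenclature (Sst -> D, Gast -> G, Cck -> I, Gip -> K,
Gcg -> L, Nts -> N, Sct -> S, Ghrl -> X, Tph1 -> EC, Hdc -> ECL,
Insl5 -> Insl5), and tests one-vs-rest differential expression with a
negative-binomial regression (log total-count offset, likelihood-ratio test,
Bonferroni correction), reporting only positively enriched genes detected in
at least 25% of the cluster's cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .normalize import NormalizedMatrix

__all__ = [
    "EmbeddingResult",
    "ClusterAssignment",
    "DEFAULT_MARKER_TABLE",
    "DEFAULT_NON_EEC_MARKERS",
    "REGION_N_PCS",
    "run_pca",
    "run_tsne",
    "kmeans_cluster",
    "annotate_clusters",
    "de_genes",
    "top_markers",
    "embed_and_cluster",
]

#: per-region PC depth used downstream of PCA
REGION_N_PCS = {"stomach": 8, "USI": 11, "LSI": 20, "caecum": 10, "LI": 11}

#: hormone/enzyme marker -> EEC subtype name
DEFAULT_MARKER_TABLE = {
    "Sst": "D", "Gast": "G", "Cck": "I", "Gip": "K", "Gcg": "L",
    "Nts": "N", "Sct": "S", "Ghrl": "X", "Tph1": "EC", "Hdc": "ECL",
    "Insl5": "Insl5",
}
#: markers of contaminating non-endocrine cells (proliferative / enterocyte)
DEFAULT_NON_EEC_MARKERS = ("Mki67", "Alpi")


@dataclass
class EmbeddingResult:
    pca_scores: np.ndarray          # cells x n_pcs
    pca_loadings: np.ndarray        # genes x n_pcs
    explained_variance_ratio: np.ndarray
    n_pcs: int
    feature_space: str              # "full" or "subspace:<name>"
    cell_ids: pd.Index
    gene_symbols: pd.Index
    tsne_coords: np.ndarray | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray              # per-cell integer label in [0, k)
    k: int
    seed: int
    cell_ids: pd.Index
    annotation: dict[int, str] = field(default_factory=dict)

    def annotated_labels(self) -> pd.Series:
        """Per-cell cell-type names (clusters without annotation -> 'unassigned')."""
        names = [self.annotation.get(int(l), "unassigned") for l in self.labels]
        return pd.Series(names, index=self.cell_ids, name="cell_type")


def run_pca(matrix: NormalizedMatrix, n_pcs: int, feature_space: str = "full") -> EmbeddingResult:
    """Exact (full-SVD) PCA of a scaled matrix.

    Deterministic up to component sign; the sign is fixed so the
    largest-magnitude loading of each component is positive.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if matrix.transform != "scaled":
        warnings.warn(f"PCA input has transform {matrix.transform!r}, expected 'scaled'")
    X = matrix.to_dense()
    max_rank = min(X.shape)
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds matrix rank bound {max_rank}; reduced")
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x n_pcs
    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_pcs)])
    flip = np.where(flip == 0, 1.0, flip)
    return EmbeddingResult(
        pca_scores=scores * flip,
        pca_loadings=loadings * flip,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_pcs=n_pcs,
        feature_space=feature_space,
        cell_ids=matrix.cell_ids,
        gene_symbols=matrix.gene_symbols,
    )


def run_tsne(scores: np.ndarray, seed: int, perplexity: float = 30.0) -> np.ndarray:
    """2-D tSNE of PC scores; seed-deterministic for a fixed backend version."""
    n = scores.shape[0]
    if n < 10:
        raise ValueError("tSNE needs >= 10 cells")
    max_perp = (n - 1) / 3.0
    if perplexity > max_perp:
        warnings.warn(f"perplexity {perplexity} too large for {n} cells; reduced to {max_perp:.1f}")
        perplexity = max_perp
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(np.asarray(scores, dtype=np.float64))
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("tSNE produced non-finite coordinates")
    return coords


def kmeans_cluster(
    embedding: EmbeddingResult | np.ndarray,
    k: int,
    seed: int,
    n_restarts: int = 10,
    resolution: float | None = None,
) -> ClusterAssignment:
    """k-means (k-means++ init, best of ``n_restarts`` by inertia) on PC scores.

    ``resolution`` belongs to modularity-based community detection, which
    k-means does not use; it is accepted for interface compatibility and
    ignored with a warning.
    """
    if resolution is not None:
        warnings.warn("k-means has no resolution parameter; value ignored")
    if isinstance(embedding, EmbeddingResult):
        scores, cell_ids = embedding.pca_scores, embedding.cell_ids
    else:
        scores = np.asarray(embedding)
        cell_ids = pd.RangeIndex(scores.shape[0])
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds number of cells {scores.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(scores)
    return ClusterAssignment(labels=labels, k=k, seed=seed, cell_ids=pd.Index(cell_ids))


def annotate_clusters(
    assignment: ClusterAssignment,
    logcpm: NormalizedMatrix,
    marker_table: dict[str, str] | None = None,
    non_eec_markers: tuple[str, ...] = DEFAULT_NON_EEC_MARKERS,
    z_cutoff: float = 1.0,
) -> ClusterAssignment:
    """Name each cluster after the marker with the highest z-scored mean
    expression (z across clusters), if that z reaches ``z_cutoff``.

    Clusters dominated by a non-EEC marker (Mki67/Alpi by default) are named
    "non-EEC" so downstream EEC-only analyses can drop them; clusters with no
    marker above the cut-off stay "unassigned".
    """
    if marker_table is None:
        marker_table = dict(DEFAULT_MARKER_TABLE)
    if not marker_table:
        raise ValueError("empty marker table")
    present = [m for m in marker_table if m in logcpm.gene_symbols]
    missing = sorted(set(marker_table) - set(present))
    if missing:
        warnings.warn(f"markers absent from matrix, skipped: {missing}")
    if not present:
        raise ValueError("no marker genes present in the matrix")
    noneec_present = [m for m in non_eec_markers if m in logcpm.gene_symbols]

    X = logcpm.subset_genes(present + noneec_present).to_dense()
    labels = assignment.labels
    clusters = np.arange(assignment.k)
    means = np.vstack([X[labels == c].mean(axis=0) if (labels == c).any() else
                       np.full(X.shape[1], np.nan) for c in clusters])
    mu = np.nanmean(means, axis=0)
    sd = np.nanstd(means, axis=0)
    z = (means - mu) / np.where(sd > 0, sd, 1.0)
    z[:, sd == 0] = 0.0

    n_markers = len(present)
    annotation: dict[int, str] = {}
    for c in clusters:
        if np.isnan(means[c]).any():
            annotation[int(c)] = "unassigned"  # empty cluster
            continue
        zm = z[c, :n_markers]
        zn = z[c, n_markers:]
        best = int(np.argmax(zm))
        if zn.size and zn.max() >= z_cutoff and zn.max() > zm[best]:
            annotation[int(c)] = "non-EEC"
        elif zm[best] >= z_cutoff:
            annotation[int(c)] = marker_table[present[best]]
        else:
            annotation[int(c)] = "unassigned"
    return ClusterAssignment(
        labels=assignment.labels, k=assignment.k, seed=assignment.seed,
        cell_ids=assignment.cell_ids, annotation=annotation,
    )


# ---------------------------------------------------------------------------
# negative-binomial differential expression


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, floor: float = 1e-3) -> float:
    """Method-of-moments NB dispersion alpha (var = mu + alpha mu^2)."""
    denom = float((mu**2).sum())
    if denom == 0:
        return floor
    alpha = float(((y - mu) ** 2 - mu).sum() / denom)
    return max(alpha, floor)


def nb_lrt(
    y: np.ndarray, indicator: np.ndarray, offset: np.ndarray, floor: float = 1e-3
) -> tuple[float, float, float, bool]:
    """One-gene NB regression count ~ intercept + indicator with offset.

    Dispersion is estimated by method of moments from group-wise rate fits
    (floored), then held fixed in both GLM fits; the p-value is a 1-df
    likelihood-ratio test.  Returns (coef, lrt_stat, p, converged).
    """
    s = np.exp(offset)
    mu0 = np.empty_like(s)
    for g in (0, 1):
        m = indicator == g
        mu0[m] = (y[m].sum() / s[m].sum()) * s[m]
    alpha = _mom_dispersion(y, mu0, floor)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    X_alt = np.column_stack([np.ones_like(offset), indicator.astype(float)])
    X_null = np.ones((y.size, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alt = sm.GLM(y, X_alt, family=fam, offset=offset).fit()
            null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
        lrt = 2.0 * (alt.llf - null.llf)
        if not np.isfinite(lrt):
            return 0.0, 0.0, 1.0, False
        lrt = max(lrt, 0.0)
        p = float(stats.chi2.sf(lrt, df=1))
        return float(alt.params[1]), float(lrt), p, True
    except Exception:
        return 0.0, 0.0, 1.0, False


def de_genes(
    matrix: ad.AnnData,
    assignment: ClusterAssignment | np.ndarray,
    cluster_id,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    positive_only: bool = True,
    pseudocount: float = 1.0,
    dispersion_floor: float = 1e-3,
    totals: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-vs-rest NB differential expression for one cluster on raw counts.

    Genes detected in fewer than ``min_pct`` of in-cluster cells are not
    tested; Bonferroni adjustment runs over the tested genes; with
    ``positive_only`` (the default) only positively enriched genes are
    reported.  log2 fold change is computed on mean CPM with a pseudocount.
    ``totals`` overrides the per-cell library sizes (useful when ``matrix``
    is a gene-subset view of a larger transcriptome).
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    in_cluster = labels == cluster_id
    if in_cluster.sum() < 3:
        raise ValueError(f"cluster {cluster_id!r} has < 3 cells")
    X = matrix.X
    X = sp.csc_matrix(X) if sp.issparse(X) else np.asarray(X)
    if totals is None:
        totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    else:
        totals = np.asarray(totals, dtype=float).ravel()
        if totals.size != X.shape[0]:
            raise ValueError("totals length must equal the number of cells")
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts; run QC first")
    offset = np.log(totals)
    indicator = in_cluster.astype(int)

    dense = X.toarray() if sp.issparse(X) else X
    detected = dense > 0
    pct_in = detected[in_cluster].mean(axis=0)
    pct_out = detected[~in_cluster].mean(axis=0)
    eligible = np.flatnonzero(pct_in >= min_pct)

    cpm_all = dense / totals[:, None] * 1e6
    mean_in = cpm_all[in_cluster].mean(axis=0)
    mean_out = cpm_all[~in_cluster].mean(axis=0)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

    rows = []
    for j in eligible:
        coef, lrt, p, converged = nb_lrt(
            dense[:, j].astype(float), indicator, offset, dispersion_floor
        )
        rows.append({
            "gene": matrix.var_names[j], "cluster": cluster_id,
            "log2fc": float(log2fc[j]), "pct_in": float(pct_in[j]),
            "pct_out": float(pct_out[j]), "coef": coef, "lrt": lrt,
            "p": p, "converged": converged,
        })
    table = pd.DataFrame(rows, columns=[
        "gene", "cluster", "log2fc", "pct_in", "pct_out", "coef", "lrt", "p", "converged",
    ])
    n_tested = len(table)
    table["p_adj"] = np.minimum(table["p"] * n_tested, 1.0) if n_tested else []
    if positive_only:
        table = table[table["coef"] > 0].reset_index(drop=True)
    return table


def top_markers(table: pd.DataFrame, n: int = 10, lfc_min: float = 1.5,
                alpha: float = 0.05) -> pd.DataFrame:
    """Top-``n`` DE genes per cluster: p_adj < alpha and log2FC > lfc_min,
    ranked by log2FC descending (may return fewer than n)."""
    passing = table[(table["p_adj"] < alpha) & (table["log2fc"] > lfc_min)]
    return (
        passing.sort_values("log2fc", ascending=False, kind="stable")
        .groupby("cluster", sort=False)
        .head(n)
        .reset_index(drop=True)
    )


def embed_and_cluster(
    scaled: NormalizedMatrix,
    n_pcs: int,
    k: int,
    seed: int,
    feature_space: str = "full",
    with_tsne: bool = True,
    perplexity: float = 30.0,
) -> tuple[EmbeddingResult, ClusterAssignment]:
    """Scale-agnostic core pipeline: PCA -> (tSNE) -> k-means on PC scores.

    Shared by the full-transcriptome and gene-set-restricted (signalling
    subspace) paths so the two differ only in the feature set.
    """
    emb = run_pca(scaled, n_pcs, feature_space=feature_space)
    if with_tsne:
        emb.tsne_coords = run_tsne(emb.pca_scores, seed=seed, perplexity=perplexity)
    assignment = kmeans_cluster(emb, k=k, seed=seed)
    return emb, assignment
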