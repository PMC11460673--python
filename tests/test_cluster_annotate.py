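"""PCA/tSNE/k-means contracts, marker annotation, NB differential expression."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from eecatlas import cluster_annotate as ca
from eecatlas import normalize as nz


def _scaled(values):
    values = np.asarray(values, dtype=float)
    return nz.NormalizedMatrix(
        values=values,
        cell_ids=pd.Index([f"c{i}" for i in range(values.shape[0])]),
        gene_symbols=pd.Index([f"g{i}" for i in range(values.shape[1])]),
        transform="scaled",
    )


def test_pca_rank1_variance():
    rng = np.random.default_rng(0)
    u = rng.normal(size=50)
    v = rng.normal(size=8)
    emb = ca.run_pca(_scaled(np.outer(u, v)), 3)
    assert emb.explained_variance_ratio[0] >= 0.999


def test_pca_reconstruction_at_full_rank():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 6))
    Xc = X - X.mean(axis=0)
    emb = ca.run_pca(_scaled(X), 6)
    recon = emb.pca_scores @ emb.pca_loadings.T
    rel = np.linalg.norm(recon - Xc) / np.linalg.norm(Xc)
    assert rel < 1e-8


def test_pca_determinism_and_sign_convention():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 10))
    e1 = ca.run_pca(_scaled(X), 4)
    e2 = ca.run_pca(_scaled(X.copy()), 4)
    np.testing.assert_array_equal(e1.pca_scores, e2.pca_scores)
    peak = np.argmax(np.abs(e1.pca_loadings), axis=0)
    assert (e1.pca_loadings[peak, np.arange(4)] > 0).all()


def test_pca_excess_components_reduced():
    rng = np.random.default_rng(3)
    with pytest.warns(UserWarning, match="reduced"):
        emb = ca.run_pca(_scaled(rng.normal(size=(5, 3))), 10)
    assert emb.n_pcs == 3


def test_tsne_determinism_and_separation():
    rng = np.random.default_rng(4)
    scores = np.vstack([
        rng.normal(0, 1, size=(40, 5)),
        rng.normal(12, 1, size=(40, 5)),
    ])
    c1 = ca.run_tsne(scores, seed=0, perplexity=10)
    c2 = ca.run_tsne(scores, seed=0, perplexity=10)
    np.testing.assert_array_equal(c1, c2)
    assert np.all(np.isfinite(c1))
    a, b = c1[:40], c1[40:]
    inter = np.linalg.norm(a.mean(0) - b.mean(0))
    intra = max(a.std(), b.std())
    assert inter > intra


def test_tsne_needs_enough_cells():
    with pytest.raises(ValueError, match=">= 10"):
        ca.run_tsne(np.zeros((5, 2)), seed=0)


def test_kmeans_planted_blobs_exact_recovery():
    rng = np.random.default_rng(5)
    centers = rng.normal(size=(5, 4)) * 50  # ~10 sigma separation
    X = np.vstack([c + rng.normal(size=(30, 4)) for c in centers])
    truth = np.repeat(np.arange(5), 30)
    assignment = ca.kmeans_cluster(X, k=5, seed=0)
    assert adjusted_rand_score(truth, assignment.labels) == 1.0


def test_kmeans_edge_cases():
    X = np.array([[0.0, 0], [1, 0], [0, 1]])
    assert set(ca.kmeans_cluster(X, k=1, seed=0).labels) == {0}
    km = ca.kmeans_cluster(X, k=3, seed=0)
    assert len(set(km.labels)) == 3  # zero inertia at k = n distinct points
    with pytest.raises(ValueError, match="exceeds"):
        ca.kmeans_cluster(X, k=4, seed=0)


def _logcpm_for_annotation(cluster_labels, marker_values, genes):
    return nz.NormalizedMatrix(
        values=np.asarray(marker_values, dtype=float),
        cell_ids=pd.Index([f"c{i}" for i in range(len(cluster_labels))]),
        gene_symbols=pd.Index(genes),
        transform="log2cpm1p",
    )


def test_annotation_picks_dominant_marker():
    labels = np.repeat([0, 1], 20)
    X = np.zeros((40, 2))
    X[labels == 0, 0] = 8.0   # Gip high in cluster 0
    X[labels == 1, 1] = 8.0   # Gcg high in cluster 1
    logm = _logcpm_for_annotation(labels, X, ["Gip", "Gcg"])
    assignment = ca.ClusterAssignment(labels=labels, k=2, seed=0, cell_ids=logm.cell_ids)
    out = ca.annotate_clusters(assignment, logm)
    assert out.annotation == {0: "K", 1: "L"}


def test_annotation_flat_markers_unassigned():
    labels = np.repeat([0, 1], 10)
    logm = _logcpm_for_annotation(labels, np.ones((20, 2)), ["Gip", "Gcg"])
    assignment = ca.ClusterAssignment(labels=labels, k=2, seed=0, cell_ids=logm.cell_ids)
    out = ca.annotate_clusters(assignment, logm)
    assert set(out.annotation.values()) == {"unassigned"}


def test_annotation_non_eec_dominant():
    labels = np.repeat([0, 1], 20)
    X = np.zeros((40, 3))
    X[labels == 0, 0] = 8.0   # Gcg cluster
    X[labels == 1, 2] = 9.0   # Alpi-dominated cluster
    logm = _logcpm_for_annotation(labels, X, ["Gcg", "Gip", "Alpi"])
    assignment = ca.ClusterAssignment(labels=labels, k=2, seed=0, cell_ids=logm.cell_ids)
    with pytest.warns(UserWarning, match="skipped"):
        out = ca.annotate_clusters(assignment, logm)
    assert out.annotation[0] == "L"
    assert out.annotation[1] == "non-EEC"


def test_annotation_empty_marker_table_rejected():
    logm = _logcpm_for_annotation([0], np.ones((1, 1)), ["Gcg"])
    assignment = ca.ClusterAssignment(
        labels=np.array([0]), k=1, seed=0, cell_ids=logm.cell_ids
    )
    with pytest.raises(ValueError, match="marker table"):
        ca.annotate_clusters(assignment, logm, marker_table={})


# ---------------------------------------------------------------------------
# differential expression


def _de_adata(rng, n_in=30, n_out=90, n_genes=20, fold=1.0, planted=()):
    size = 2.0
    base = rng.lognormal(1.5, 0.8, n_genes)
    mu = np.tile(base, (n_in + n_out, 1))
    mu[:n_in, list(planted)] *= fold
    counts = rng.negative_binomial(size, size / (size + mu))
    counts += 1  # avoid zero-total cells in tiny instances
    a = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_in + n_out)]),
        var=pd.DataFrame(index=[f"g{i}" for i in range(n_genes)]),
    )
    labels = np.array([1] * n_in + [0] * (n_out))
    return a, labels


def test_de_lrt_matches_grid_search_oracle(oracles):
    """LRT statistic agrees with an independent grid-search maximum-likelihood
    oracle on a 20-cell, 5-gene instance within 1e-4."""
    rng = np.random.default_rng(10)
    a, labels = _de_adata(rng, n_in=8, n_out=12, n_genes=5, fold=4.0, planted=(0,))
    table = ca.de_genes(a, labels, 1, min_pct=0.0, positive_only=False)
    X = a.X.toarray().astype(float)
    totals = X.sum(axis=1)
    offset = np.log(totals)
    for _, row in table.iterrows():
        j = a.var_names.get_loc(row.gene)
        y = X[:, j]
        # reproduce the fixed dispersion exactly as the implementation pins it
        s = totals
        mu0 = np.empty_like(s, dtype=float)
        for g in (0, 1):
            m = labels == g
            mu0[m] = (y[m].sum() / s[m].sum()) * s[m]
        alpha = max(float(((y - mu0) ** 2 - mu0).sum() / (mu0**2).sum()), 1e-3)
        lrt_oracle = oracles["nb_lrt"](y, labels, offset, alpha)
        assert row.lrt == pytest.approx(lrt_oracle, abs=1e-4), row.gene


def test_de_min_pct_gate():
    """A gene detected in 10% of cluster cells is not tested."""
    rng = np.random.default_rng(11)
    a, labels = _de_adata(rng, n_in=20, n_out=60, n_genes=5)
    X = a.X.toarray()
    X[:, 0] = 0
    X[labels == 1, 0] = 0
    X[np.flatnonzero(labels == 1)[:2], 0] = 50  # 10% of the cluster
    a.X = sp.csr_matrix(X)
    table = ca.de_genes(a, labels, 1, positive_only=False)
    assert "g0" not in set(table.gene)


def test_de_positive_enrichment_only():
    """A gene strongly lower in-cluster is absent from the default output."""
    rng = np.random.default_rng(12)
    a, labels = _de_adata(rng, fold=0.05, planted=(3,))
    table = ca.de_genes(a, labels, 1)
    assert "g3" not in set(table.gene)
    full = ca.de_genes(a, labels, 1, positive_only=False)
    assert "g3" in set(full.gene)


def test_de_bonferroni_exact():
    rng = np.random.default_rng(13)
    a, labels = _de_adata(rng)
    table = ca.de_genes(a, labels, 1, positive_only=False)
    n = len(table)
    np.testing.assert_allclose(table.p_adj, np.minimum(table.p * n, 1.0))
    assert (table.p_adj >= table.p - 1e-15).all()


def test_de_planted_marker_detected_and_ranked():
    rng = np.random.default_rng(14)
    a, labels = _de_adata(rng, n_in=60, n_out=180, fold=8.0, planted=(7,))
    table = ca.de_genes(a, labels, 1)
    top = ca.top_markers(table, n=10, lfc_min=1.5)
    assert len(top) >= 1
    assert top.iloc[0].gene == "g7"


def test_de_small_cluster_rejected():
    rng = np.random.default_rng(15)
    a, labels = _de_adata(rng)
    labels = labels.copy()
    labels[labels == 1] = 0
    labels[:2] = 1
    with pytest.raises(ValueError, match="< 3 cells"):
        ca.de_genes(a, labels, 1)


def test_top_markers_contracts():
    table = pd.DataFrame({
        "gene": [f"g{i}" for i in range(12)],
        "cluster": [0] * 12,
        "log2fc": np.linspace(1.6, 4.0, 12),
        "p": [1e-6] * 12,
        "p_adj": [1e-4] * 12,
    })
    top = ca.top_markers(table, n=10)
    assert len(top) == 10
    assert top.iloc[0].log2fc == pytest.approx(4.0)
    none_pass = ca.top_markers(table.assign(p_adj=0.5), n=10)
    assert none_pass.empty
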