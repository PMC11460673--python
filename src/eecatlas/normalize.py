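"""Library-size normalization and the expression scales fed downstream.

The pipeline's working scales are counts-per-million (CPM), log2(CPM + 1),
an optional covariate-residualized version of the log scale (ordinary
least-squares removal of %mito, standing in for a regularized-NB
normalization with the same stated intent), and per-gene z-scaling ahead of
PCA.  Variable genes are ranked by standardized variance of log2(CPM + 1)
against a 10-bin running-median mean-variance trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import GeneSet

__all__ = [
    "NormalizedMatrix",
    "cpm",
    "log_norm",
    "residualize_covariate",
    "scale_genes",
    "variable_gene_scores",
    "select_variable_genes",
]


@dataclass
class NormalizedMatrix:
    """A cells x genes real matrix with its transform tag and provenance."""

    values: np.ndarray | sp.spmatrix
    cell_ids: pd.Index
    gene_symbols: pd.Index
    transform: str  # cpm | log2cpm1p | residualized | scaled
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def subset_genes(self, symbols) -> "NormalizedMatrix":
        idx = self.gene_symbols.get_indexer(symbols)
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise KeyError(f"genes absent from matrix: {missing}")
        return NormalizedMatrix(
            values=self.values[:, idx],
            cell_ids=self.cell_ids,
            gene_symbols=pd.Index(symbols),
            transform=self.transform,
            cell_meta=self.cell_meta,
            provenance={**self.provenance, "subset": list(symbols)},
        )


def cpm(matrix: ad.AnnData | NormalizedMatrix) -> NormalizedMatrix:
    """Counts per million: count / cell total x 1e6.

    Refuses input that is already CPM-normalized; zero-total cells yield zero
    rows with a warning.
    """
    if isinstance(matrix, NormalizedMatrix):
        raise ValueError(
            f"cpm expects raw counts, got a {matrix.transform!r}-transformed matrix"
        )
    X = matrix.X
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-total cells produce zero CPM rows")
    inv = np.divide(1e6, totals, out=np.zeros_like(totals), where=~zero)
    if sp.issparse(X):
        values = sp.diags(inv) @ X.tocsr()
        values = values.tocsr()
    else:
        values = np.asarray(X, dtype=float) * inv[:, None]
    return NormalizedMatrix(
        values=values,
        cell_ids=matrix.obs_names.copy(),
        gene_symbols=matrix.var_names.copy(),
        transform="cpm",
        cell_meta=matrix.obs.copy(),
        provenance={"source": "counts"},
    )


def log_norm(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """log2(CPM + 1); requires a cpm-tagged input."""
    if matrix.transform != "cpm":
        raise ValueError(f"log_norm expects cpm input, got {matrix.transform!r}")
    v = matrix.values
    if sp.issparse(v):
        v = v.tocsr().copy()
        v.data = np.log2(v.data + 1.0)
    else:
        v = np.log2(np.asarray(v) + 1.0)
    return NormalizedMatrix(
        values=v,
        cell_ids=matrix.cell_ids,
        gene_symbols=matrix.gene_symbols,
        transform="log2cpm1p",
        cell_meta=matrix.cell_meta,
        provenance={**matrix.provenance, "log": "log2(x+1)"},
    )


def residualize_covariate(
    matrix: NormalizedMatrix, covariate: np.ndarray
) -> NormalizedMatrix:
    """Remove a per-cell covariate from every gene by OLS, keeping the mean.

    Per gene the model value ~ intercept + covariate is fit; the returned
    values are residuals plus the fitted intercept (covariate centred, so
    per-gene means are unchanged and residuals are exactly orthogonal to the
    covariate).  A constant covariate is an identity transform with warning.
    """
    cov = np.asarray(covariate, dtype=float).ravel()
    if cov.size != matrix.shape[0]:
        raise ValueError("covariate length must equal the number of cells")
    X = matrix.to_dense().astype(float)
    cov_c = cov - cov.mean()
    denom = float(cov_c @ cov_c)
    if denom == 0.0:
        warnings.warn("constant covariate: residualization is the identity")
        values = X
    else:
        beta = (X.T @ cov_c) / denom  # per-gene slope
        values = X - np.outer(cov_c, beta)
    return NormalizedMatrix(
        values=values,
        cell_ids=matrix.cell_ids,
        gene_symbols=matrix.gene_symbols,
        transform="residualized",
        cell_meta=matrix.cell_meta,
        provenance={**matrix.provenance, "residualized_against": "covariate"},
    )


def scale_genes(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene z-scaling (mean 0, unit population variance); constant genes
    are set to 0."""
    X = matrix.to_dense().astype(float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    values = (X - mean) / sd_safe
    values[:, sd == 0] = 0.0
    return NormalizedMatrix(
        values=values,
        cell_ids=matrix.cell_ids,
        gene_symbols=matrix.gene_symbols,
        transform="scaled",
        cell_meta=matrix.cell_meta,
        provenance={**matrix.provenance, "scaled": True},
    )


def variable_gene_scores(matrix: ad.AnnData, n_bins: int = 10) -> pd.Series:
    """Standardized variance of log2(CPM+1) per gene.

    Genes are ordered by mean expression and split into ``n_bins``
    equal-count bins; each gene's variance is divided by its bin's median
    variance (the running-median mean-variance trend), so high scores mark
    genes more variable than same-abundance peers.
    """
    logm = log_norm(cpm(matrix))
    X = logm.to_dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    trend = np.empty_like(var)
    for b in bins:
        med = np.median(var[b])
        trend[b] = med if med > 0 else np.nan
    trend = np.where(np.isnan(trend), np.nanmax(trend) if np.isfinite(np.nanmax(trend)) else 1.0, trend)
    score = var / np.where(trend > 0, trend, 1.0)
    return pd.Series(score, index=matrix.var_names, name="standardized_variance")


def select_variable_genes(matrix: ad.AnnData, n: int) -> GeneSet:
    """Top-``n`` genes by standardized variance (ties broken by gene order)."""
    scores = variable_gene_scores(matrix)
    if n > len(scores):
        warnings.warn(f"requested {n} variable genes but only {len(scores)} present")
        n = len(scores)
    order = np.argsort(-scores.to_numpy(), kind="stable")[:n]
    return GeneSet(name=f"hvg{n}", symbols=tuple(scores.index[order]))
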