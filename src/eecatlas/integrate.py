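"""Simplified CCA-driven integration of per-region datasets.

The joint embedding is the named core of the reference method: over a
shared feature set of 2000 integration features (union of per-dataset
variable genes), the cells x cells cross-product K = X1 X2^T of the scaled
expression matrices is decomposed by truncated SVD, and the L2-normalized
rows of U and V place the two datasets' cells in a common canonical space
in which corresponding cell states align irrespective of per-gene batch
shifts.  Multiple datasets are merged pairwise onto the largest (reference)
dataset in decreasing-size order.  Anchor finding/weighting and expression
correction of the full published pipeline are deliberately out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .io_formats import GeneSet
from .normalize import NormalizedMatrix, variable_gene_scores

__all__ = ["IntegrationResult", "integration_features", "cca_pair", "integrate_all"]


@dataclass
class IntegrationResult:
    embedding: np.ndarray                  # all cells x n_cc, rows L2-normalized
    canonical_correlations: np.ndarray     # s_i / s_max, non-increasing in [0, 1]
    dataset_of_origin: np.ndarray          # per-cell dataset label
    cell_ids: pd.Index
    features: tuple[str, ...] = ()
    merge_order: list[str] = field(default_factory=list)


def integration_features(datasets: list[ad.AnnData], n: int = 2000) -> GeneSet:
    """Integration feature set: union of per-dataset variable genes, ranked by
    summed standardized-variance rank, truncated to ``n``, and intersected
    with the genes present in every dataset."""
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets")
    shared = set(datasets[0].var_names)
    for d in datasets[1:]:
        shared &= set(d.var_names)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared across datasets")

    rank_sum: dict[str, float] = {}
    union: set[str] = set()
    for d in datasets:
        scores = variable_gene_scores(d)
        order = scores.sort_values(ascending=False, kind="stable")
        union |= set(order.index)
        for r, g in enumerate(order.index):
            rank_sum[g] = rank_sum.get(g, 0.0) + r
    # genes absent from a dataset rank last there
    for d in datasets:
        absent = union - set(d.var_names)
        for g in absent:
            rank_sum[g] += float(d.n_vars)

    candidates = sorted(union & shared, key=lambda g: (rank_sum[g], g))
    if n > len(candidates):
        warnings.warn(f"requested {n} integration features, only {len(candidates)} available")
        n = len(candidates)
    return GeneSet(name=f"integration{n}", symbols=tuple(candidates[:n]))


def _as_array(X) -> np.ndarray:
    return X.to_dense() if isinstance(X, NormalizedMatrix) else np.asarray(X, dtype=float)


def _svd_embed(K: np.ndarray, n_cc: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic truncated SVD of K with the largest-|entry|-positive sign
    convention, returning (U, s, V)."""
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_cc > rank:
        warnings.warn(f"rank {rank} < requested {n_cc} components; reduced")
        n_cc = max(rank, 1)
    U, s, V = U[:, :n_cc], s[:n_cc], Vt[:n_cc].T
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n_cc)])
    flip = np.where(flip == 0, 1.0, flip)
    return U * flip, s, V * flip


def _l2_normalize(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    return rows / np.where(norms > 0, norms, 1.0)


def cca_pair(
    X1: NormalizedMatrix | np.ndarray,
    X2: NormalizedMatrix | np.ndarray,
    n_cc: int = 20,
    labels: tuple[str, str] = ("dataset1", "dataset2"),
) -> IntegrationResult:
    """Joint canonical embedding of two scaled matrices on shared features.

    K = X1 X2^T is SVD-truncated to ``n_cc``; cell embeddings are the
    L2-normalized rows of U (dataset 1) and V (dataset 2); canonical
    correlations are the singular values normalized by the largest.
    """
    A, B = _as_array(X1), _as_array(X2)
    if A.shape[1] != B.shape[1]:
        raise ValueError("datasets must share the same feature set")
    n_cc = min(n_cc, A.shape[0], B.shape[0], A.shape[1])
    K = A @ B.T
    U, s, V = _svd_embed(K, n_cc)
    emb = _l2_normalize(np.vstack([U, V]))
    ids1 = X1.cell_ids if isinstance(X1, NormalizedMatrix) else pd.RangeIndex(A.shape[0])
    ids2 = X2.cell_ids if isinstance(X2, NormalizedMatrix) else pd.RangeIndex(B.shape[0])
    return IntegrationResult(
        embedding=emb,
        canonical_correlations=s / s[0] if s.size else s,
        dataset_of_origin=np.array([labels[0]] * A.shape[0] + [labels[1]] * B.shape[0]),
        cell_ids=pd.Index(list(ids1) + list(ids2)),
        merge_order=list(labels),
    )


def integrate_all(
    datasets: dict[str, NormalizedMatrix | np.ndarray],
    n_cc: int = 20,
    features: tuple[str, ...] = (),
) -> IntegrationResult:
    """Merge >= 2 scaled datasets pairwise onto the largest (reference).

    Datasets are concatenated onto the growing reference in decreasing-size
    order; each merge is a fresh cross-product SVD, so the final canonical
    space covers every cell.
    """
    if len(datasets) < 2:
        raise ValueError("nothing to integrate: need >= 2 datasets")
    arrays = {k: _as_array(v) for k, v in datasets.items()}
    ids = {
        k: (v.cell_ids if isinstance(v, NormalizedMatrix) else
            pd.Index([f"{k}:{i}" for i in range(arrays[k].shape[0])]))
        for k, v in datasets.items()
    }
    n_feat = {a.shape[1] for a in arrays.values()}
    if len(n_feat) != 1:
        raise ValueError("datasets must share the same feature set")

    order = sorted(arrays, key=lambda k: (-arrays[k].shape[0], k))
    ref_key = order[0]
    merged = arrays[ref_key]
    merged_ids = list(ids[ref_key])
    merged_origin = [ref_key] * merged.shape[0]
    result = None
    for key in order[1:]:
        nxt = arrays[key]
        k_cc = min(n_cc, merged.shape[0], nxt.shape[0], merged.shape[1])
        K = merged @ nxt.T
        U, s, V = _svd_embed(K, k_cc)
        emb = _l2_normalize(np.vstack([U, V]))
        merged = np.vstack([merged, nxt])
        merged_ids += list(ids[key])
        merged_origin += [key] * nxt.shape[0]
        result = IntegrationResult(
            embedding=emb,
            canonical_correlations=s / s[0] if s.size else s,
            dataset_of_origin=np.array(merged_origin),
            cell_ids=pd.Index(merged_ids),
            features=tuple(features),
            merge_order=order[: order.index(key) + 1],
        )
    return result
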