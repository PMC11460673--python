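"""Re-embedding and re-clustering in the GPCR cell-signalling gene subspace.

Instead of variable genes, only a curated list of receptor and signalling
genes (GPCRs, G-protein subunits and regulators, GPCR kinases, adenylate
cyclases, phosphodiesterases, beta-arrestins, PLC and PKA/PKC isoforms,
A-kinase anchoring proteins, ion channels, calcium-release machinery and
ryanodine receptors) defines the feature space; cells are scaled, reduced to
10 PCs, tSNE-embedded and k-means-clustered exactly as in the full pipeline,
so any separation seen is attributable to signalling-gene expression alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster_annotate import ClusterAssignment, EmbeddingResult, de_genes, embed_and_cluster
from .io_formats import GeneSet
from .normalize import NormalizedMatrix, scale_genes

__all__ = [
    "SignallingGeneSet",
    "load_signalling_gene_set",
    "subspace_embed",
    "subspace_cluster",
    "subspace_de",
    "cross_space_concordance",
]


@dataclass(frozen=True)
class SignallingGeneSet:
    """A gene set with a per-symbol signalling-pathway category tag."""

    name: str
    symbols: tuple[str, ...]
    categories: dict[str, str]

    def as_gene_set(self) -> GeneSet:
        return GeneSet(name=self.name, symbols=self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)


def load_signalling_gene_set(path: str | Path | None = None) -> SignallingGeneSet:
    """Load a signalling gene set (symbol<TAB>category lines, '#' comments).

    Without a path, the packaged curated default (v1) is used.
    """
    if path is None:
        src = resources.files("eecatlas").joinpath("data/gpcr_signalling.txt")
        text = src.read_text()
        name = "gpcr_signalling_v1"
    else:
        text = Path(path).read_text()
        name = Path(path).stem
    symbols: list[str] = []
    categories: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        sym = parts[0].strip()
        if sym in categories:
            continue
        symbols.append(sym)
        categories[sym] = parts[1].strip() if len(parts) > 1 else "uncategorized"
    if not symbols:
        raise ValueError("signalling gene set is empty after parsing")
    return SignallingGeneSet(name=name, symbols=tuple(symbols), categories=categories)


def _restrict(matrix: NormalizedMatrix, gene_set) -> tuple[NormalizedMatrix, list[str]]:
    symbols = gene_set.symbols if hasattr(gene_set, "symbols") else tuple(gene_set)
    present = [s for s in symbols if s in matrix.gene_symbols]
    missing = [s for s in symbols if s not in matrix.gene_symbols]
    if len(present) < 2:
        raise ValueError(
            f"fewer than 2 gene-set symbols present in the matrix; missing: {missing}"
        )
    return matrix.subset_genes(present), missing


def subspace_embed(
    matrix: NormalizedMatrix,
    gene_set: SignallingGeneSet | GeneSet,
    n_pcs: int = 10,
    seed: int = 0,
    with_tsne: bool = True,
) -> EmbeddingResult:
    """Scale -> PCA(n_pcs) -> tSNE on the matrix restricted to the gene set.

    The input is unscaled normalized expression (log2(CPM+1), residualized,
    or an integrated representation); scaling happens after restriction so
    the subspace path matches the full pipeline exactly when the gene set
    covers all genes.
    """
    restricted, _ = _restrict(matrix, gene_set)
    name = getattr(gene_set, "name", "custom")
    emb, _ = embed_and_cluster(
        scale_genes(restricted), n_pcs=n_pcs, k=1, seed=seed,
        feature_space=f"subspace:{name}", with_tsne=with_tsne,
    )
    return emb


def subspace_cluster(
    matrix: NormalizedMatrix,
    gene_set: SignallingGeneSet | GeneSet,
    n_pcs: int = 10,
    k: int = 10,
    seed: int = 0,
    with_tsne: bool = True,
) -> tuple[EmbeddingResult, ClusterAssignment]:
    """Full subspace pipeline: restriction -> scale -> PCA -> tSNE -> k-means."""
    restricted, _ = _restrict(matrix, gene_set)
    name = getattr(gene_set, "name", "custom")
    return embed_and_cluster(
        scale_genes(restricted), n_pcs=n_pcs, k=k, seed=seed,
        feature_space=f"subspace:{name}", with_tsne=with_tsne,
    )


def subspace_de(
    matrix: ad.AnnData,
    assignment: ClusterAssignment,
    gene_set: SignallingGeneSet | GeneSet,
    cluster_id=None,
    **kwargs,
) -> pd.DataFrame:
    """One-vs-rest NB differential expression restricted to the gene set.

    Delegates to the full DE machinery on the gene-set columns only (same
    min.pct / positive-enrichment filters); ``cluster_id=None`` tests every
    cluster with >= 3 cells.
    """
    symbols = gene_set.symbols if hasattr(gene_set, "symbols") else tuple(gene_set)
    present = [s for s in symbols if s in matrix.var_names]
    if not present:
        raise ValueError("no gene-set symbols present in the matrix")
    # library sizes come from the full transcriptome, not the gene subset
    totals = np.asarray(matrix.X.sum(axis=1)).ravel()
    sub = matrix[:, present].copy()
    if cluster_id is not None:
        return de_genes(sub, assignment, cluster_id, totals=totals, **kwargs)
    tables = []
    for c in range(assignment.k):
        if (assignment.labels == c).sum() >= 3:
            tables.append(de_genes(sub, assignment, c, totals=totals, **kwargs))
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def cross_space_concordance(
    full: ClusterAssignment | np.ndarray,
    subspace: ClusterAssignment | np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index between two clusterings of
    the same cells (e.g. full-transcriptome vs signalling-subspace)."""
    a = full.labels if isinstance(full, ClusterAssignment) else np.asarray(full)
    b = subspace.labels if isinstance(subspace, ClusterAssignment) else np.asarray(subspace)
    if isinstance(full, ClusterAssignment) and isinstance(subspace, ClusterAssignment):
        if not full.cell_ids.equals(subspace.cell_ids):
            raise ValueError("assignments cover different cell sets")
    elif a.shape != b.shape:
        raise ValueError("assignments cover different cell sets")
    table = pd.crosstab(pd.Series(a, name="full"), pd.Series(b, name="subspace"))
    return table, float(adjusted_rand_score(a, b))
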