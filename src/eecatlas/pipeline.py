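"""End-to-end orchestration of the atlas analysis on a multi-region matrix.

Order of operations per region: gene filter -> cell filter (strict %mito
cut-off) -> CPM -> log2(CPM+1) -> %mito residualization -> scaling -> PCA
(per-region PC depth) -> k-means (k = 10) -> marker annotation -> one-vs-rest
NB differential expression.  Hormone positivity runs on the CPM matrix over
all regions combined (stomach-scoped Sst/Ghrl thresholds), and integration
merges the per-region scaled matrices on shared integration features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import pandas as pd

from . import qc
from .cluster_annotate import (
    REGION_N_PCS,
    ClusterAssignment,
    EmbeddingResult,
    annotate_clusters,
    de_genes,
    embed_and_cluster,
)
from .hormone_threshold import (
    HormonePanel,
    build_threshold_table,
    call_positive,
)
from .normalize import cpm, log_norm, residualize_covariate, scale_genes

__all__ = ["RegionResult", "run_region_pipeline", "run_positivity", "run_atlas"]


@dataclass
class RegionResult:
    region: str
    adata: ad.AnnData               # QC-filtered counts
    embedding: EmbeddingResult
    assignment: ClusterAssignment
    de_tables: dict[int, pd.DataFrame] = field(default_factory=dict)


def run_region_pipeline(
    adata: ad.AnnData,
    seed: int,
    n_pcs: int | None = None,
    k: int = 10,
    qc_config: qc.QCConfig | None = None,
    with_tsne: bool = False,
    with_de: bool = False,
    residualize_mito: bool = True,
) -> RegionResult:
    """QC, normalize, embed, cluster and annotate one region's cells."""
    region = str(adata.obs["region"].unique()[0])
    qc.compute_mito_fraction(adata, (qc_config or qc.QCConfig()).mito_prefix)
    filtered = qc.filter_cells(qc.filter_genes(adata, qc_config), qc_config)

    logm = log_norm(cpm(filtered))
    if residualize_mito:
        logm = residualize_covariate(logm, filtered.obs["pct_mito"].to_numpy())
    scaled = scale_genes(logm)

    if n_pcs is None:
        n_pcs = REGION_N_PCS.get(region, 10)
    emb, assignment = embed_and_cluster(scaled, n_pcs=n_pcs, k=k, seed=seed, with_tsne=with_tsne)
    assignment = annotate_clusters(assignment, logm)

    result = RegionResult(region=region, adata=filtered, embedding=emb, assignment=assignment)
    if with_de:
        for c in range(assignment.k):
            if (assignment.labels == c).sum() >= 3:
                result.de_tables[c] = de_genes(filtered, assignment, c)
    return result


def run_positivity(
    adata: ad.AnnData, panel: HormonePanel | None = None, n_bins: int = 256
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Huang thresholds (all regions combined, with region exceptions) and the
    resulting positivity matrix, from raw multi-region counts."""
    cpm_nm = cpm(adata)
    table = build_threshold_table(cpm_nm, panel, n_bins=n_bins)
    positivity = call_positive(cpm_nm, table, panel)
    return table, positivity


def run_atlas(
    adata: ad.AnnData,
    seed: int,
    panel: HormonePanel | None = None,
    qc_config: qc.QCConfig | None = None,
    with_tsne: bool = False,
    with_de: bool = False,
) -> tuple[dict[str, RegionResult], pd.DataFrame, pd.DataFrame]:
    """Full atlas pass: per-region pipelines plus combined hormone positivity.

    Returns (per-region results, threshold table, positivity matrix).
    """
    per_region = {
        region: run_region_pipeline(
            sub, seed=seed, qc_config=qc_config, with_tsne=with_tsne, with_de=with_de
        )
        for region, sub in qc.split_by_region(adata).items()
    }
    table, positivity = run_positivity(adata, panel)
    return per_region, table, positivity
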