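"""Per-region gene and cell quality-control filters.

Genes must be detected (count > 0) in at least 3 cells and carry a minimum
total raw count across the region's cells (500 for USI/LSI, 1000 for
stomach/caecum/LI).  Cells must have a mitochondrial read fraction strictly
below the region's cut-off (20% for USI/LSI/LI, 25% for stomach/caecum).
Filters run genes first, then cells, applied once without iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np

log = logging.getLogger(__name__)

__all__ = ["QCConfig", "compute_mito_fraction", "filter_genes", "filter_cells", "split_by_region"]

DEFAULT_MIN_TOTAL = {"USI": 500, "LSI": 500, "stomach": 1000, "caecum": 1000, "LI": 1000}
DEFAULT_MAX_MITO = {"USI": 0.20, "LSI": 0.20, "LI": 0.20, "stomach": 0.25, "caecum": 0.25}


@dataclass
class QCConfig:
    min_cells_per_gene: int = 3
    min_total_counts_per_gene: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_TOTAL)
    )
    max_mito_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_MITO)
    )
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be >= 0")
        if any(v < 0 for v in self.min_total_counts_per_gene.values()):
            raise ValueError("min_total_counts_per_gene must be >= 0")
        if any(not 0 <= v <= 1 for v in self.max_mito_fraction.values()):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def _single_region(adata: ad.AnnData) -> str:
    if "region" not in adata.obs:
        raise ValueError("matrix lacks a per-cell 'region' label")
    regions = adata.obs["region"].unique()
    regions = [r for r in regions if str(r) != "nan"]
    if len(regions) != 1:
        raise ValueError(
            f"QC filters are per-region; split the matrix first (found {list(regions)})"
        )
    return str(regions[0])


def split_by_region(adata: ad.AnnData) -> dict[str, ad.AnnData]:
    """Split a multi-region matrix into per-region copies."""
    if "region" not in adata.obs:
        raise ValueError("matrix lacks a per-cell 'region' label")
    return {
        str(r): adata[adata.obs["region"] == r].copy()
        for r in adata.obs["region"].unique()
    }


def compute_mito_fraction(adata: ad.AnnData, mito_prefix: str = "mt-") -> np.ndarray:
    """Per-cell fraction of counts on mitochondria-encoded genes.

    Mito genes are identified by a case-insensitive symbol prefix.  The
    fraction is stored in ``obs['pct_mito']`` (on the 0-1 scale) and the flag
    in ``var['mito']``; zero-total cells get fraction 0 with a warning.
    """
    mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in adata.var_names])
    adata.var["mito"] = mito
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros_like(total)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero total counts; %mito set to 0")
    frac = np.divide(mito_counts, total, out=np.zeros_like(total, dtype=float), where=~zero)
    adata.obs["pct_mito"] = frac
    return frac


def filter_genes(adata: ad.AnnData, config: QCConfig | None = None) -> ad.AnnData:
    """Keep genes detected in >= min_cells cells (inclusive) AND with total
    raw counts >= the region's threshold (inclusive)."""
    config = config or QCConfig()
    region = _single_region(adata)
    if region not in config.min_total_counts_per_gene:
        raise ValueError(f"no min_total_counts_per_gene threshold for region {region!r}")
    min_total = config.min_total_counts_per_gene[region]

    X = adata.X
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    keep = (n_detected >= config.min_cells_per_gene) & (totals >= min_total)
    log.info(
        "filter_genes[%s]: kept %d/%d (detection rule removed %d, total rule removed %d)",
        region, int(keep.sum()), adata.n_vars,
        int((n_detected < config.min_cells_per_gene).sum()),
        int((totals < min_total).sum()),
    )
    return adata[:, keep].copy()


def filter_cells(adata: ad.AnnData, config: QCConfig | None = None) -> ad.AnnData:
    """Keep cells whose mito fraction is strictly below the region's cut-off."""
    config = config or QCConfig()
    region = _single_region(adata)
    if region not in config.max_mito_fraction:
        raise ValueError(f"no max_mito_fraction threshold for region {region!r}")
    if "pct_mito" not in adata.obs:
        compute_mito_fraction(adata, config.mito_prefix)
    keep = adata.obs["pct_mito"].to_numpy() < config.max_mito_fraction[region]
    log.info("filter_cells[%s]: kept %d/%d", region, int(keep.sum()), adata.n_obs)
    return adata[keep].copy()
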