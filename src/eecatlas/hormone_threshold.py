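"""Huang fuzzy thresholding of hormone CPM distributions and positivity calls.

Huang's method (the "Huang2" variant of image-analysis auto-thresholding,
here applied to per-gene CPM histograms) picks the cut that minimizes the
total fuzzy entropy of the two classes it induces: each histogram bin gets a
membership u = 1 / (1 + |x - mu_class| / C) to its class mean (C = data
range), and the Shannon-type fuzziness S(u) = -u ln u - (1-u) ln(1-u) is
summed over bins weighted by their counts.  Thresholds are computed per gene
from the CPM distribution over all regions combined, except genes declared
as region exceptions (Sst and Ghrl in the stomach, which show high ambient
expression there) which additionally get thresholds from that region's cells
only.  A cell is positive for a hormone iff its CPM is strictly greater than
the applicable threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix

__all__ = [
    "HormonePanel",
    "huang_threshold",
    "build_threshold_table",
    "call_positive",
    "coexpression_summary",
    "venn_counts",
]

DEFAULT_PANEL_SYMBOLS = (
    "Gcg", "Cck", "Sct", "Pyy", "Nts", "Insl5", "Sst",
    "Ghrl", "Gip", "Gast", "Ppy", "Tph1", "Hdc",
)
#: genes whose high gastric background warrants a stomach-only threshold
DEFAULT_REGION_EXCEPTIONS = {"Sst": ("stomach",), "Ghrl": ("stomach",)}


@dataclass(frozen=True)
class HormonePanel:
    symbols: tuple[str, ...] = DEFAULT_PANEL_SYMBOLS
    region_exceptions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_EXCEPTIONS)
    )

    def __post_init__(self) -> None:
        unknown = set(self.region_exceptions) - set(self.symbols)
        if unknown:
            raise ValueError(f"exception genes not in panel: {sorted(unknown)}")


def huang_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Fuzzy-entropy (Huang) threshold of a non-negative sample, on its own scale.

    Values are binned into ``n_bins`` equal-width bins over [min, max]; for
    every candidate cut t the class means below/above t are taken from the
    histogram (bin centres), memberships u = 1/(1 + |x - mu| / C) with
    C = max - min, and the cut minimizing sum h(bin) * S(u) is chosen
    (ties -> lowest t).  Returns the upper edge of the chosen bin.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.min(values) == np.max(values):
        raise ValueError("degenerate distribution: need >= 2 distinct values")
    lo, hi = float(np.min(values)), float(np.max(values))
    h, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    h = h.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    C = hi - lo

    n0 = np.cumsum(h)                       # counts in bins <= t
    w0 = np.cumsum(h * centers)
    n_total, w_total = n0[-1], w0[-1]
    valid = (n0 > 0) & (n0 < n_total)       # both classes non-empty
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = w0 / n0
        mu1 = (w_total - w0) / (n_total - n0)

    def entropy(u: np.ndarray) -> np.ndarray:
        # S(u) = -u ln u - (1-u) ln(1-u), S(0)=S(1)=0; u is always in [0.5, 1]
        out = np.zeros_like(u)
        inner = (u > 0) & (u < 1)
        ui = u[inner]
        out[inner] = -ui * np.log(ui) - (1 - ui) * np.log(1 - ui)
        return out

    # broadcast: rows = candidate t, cols = bins
    dist0 = np.abs(centers[None, :] - mu0[:, None]) / C
    dist1 = np.abs(centers[None, :] - mu1[:, None]) / C
    u0 = 1.0 / (1.0 + dist0)
    u1 = 1.0 / (1.0 + dist1)
    below = np.arange(n_bins)[None, :] <= np.arange(n_bins)[:, None]
    S = np.where(below, entropy(u0), entropy(u1))
    E = (h[None, :] * S).sum(axis=1)
    E[~valid] = np.inf
    if not np.isfinite(E).any():
        raise ValueError("degenerate distribution: no valid threshold candidate")
    t = int(np.argmin(E))  # argmin takes the lowest index on ties
    return float(edges[t + 1])


def build_threshold_table(
    cpm_matrix: NormalizedMatrix,
    panel: HormonePanel | None = None,
    n_bins: int = 256,
) -> pd.DataFrame:
    """One combined (all-regions) Huang threshold per panel gene, plus
    region-scoped thresholds for the declared exception (gene, region) pairs.

    Returns a tidy table (gene, scope, threshold, n_cells, n_bins,
    bin_width); panel genes absent from the matrix are recorded with NaN and
    excluded downstream.
    """
    if cpm_matrix.transform != "cpm":
        raise ValueError("thresholds are computed on the CPM scale")
    panel = panel or HormonePanel()
    regions = (
        cpm_matrix.cell_meta["region"].astype(str).to_numpy()
        if "region" in cpm_matrix.cell_meta
        else None
    )
    rows = []
    for gene in panel.symbols:
        if gene not in cpm_matrix.gene_symbols:
            warnings.warn(f"panel gene {gene!r} absent from matrix; recorded as missing")
            rows.append({"gene": gene, "scope": "combined", "threshold": np.nan,
                         "n_cells": 0, "n_bins": n_bins, "bin_width": np.nan})
            continue
        col = cpm_matrix.subset_genes([gene]).to_dense().ravel()
        scopes = [("combined", np.ones(col.size, dtype=bool))]
        for region in panel.region_exceptions.get(gene, ()):
            if regions is None:
                raise ValueError("region exceptions require per-cell region labels")
            scopes.append((region, regions == region))
        for scope, mask in scopes:
            vals = col[mask]
            if vals.size < 2 or vals.min() == vals.max():
                warnings.warn(f"{gene}/{scope}: degenerate CPM distribution; threshold missing")
                thr, width = np.nan, np.nan
            else:
                thr = huang_threshold(vals, n_bins=n_bins)
                width = (vals.max() - vals.min()) / n_bins
            rows.append({"gene": gene, "scope": scope, "threshold": thr,
                         "n_cells": int(mask.sum()), "n_bins": n_bins, "bin_width": width})
    return pd.DataFrame(rows)


def call_positive(
    cpm_matrix: NormalizedMatrix,
    table: pd.DataFrame,
    panel: HormonePanel | None = None,
) -> pd.DataFrame:
    """Boolean cells x panel-genes positivity: CPM strictly greater than the
    applicable threshold (region-scoped for exception (gene, region) pairs,
    combined otherwise)."""
    if cpm_matrix.transform != "cpm":
        raise ValueError("positivity is called on the CPM scale")
    panel = panel or HormonePanel()
    regions = (
        cpm_matrix.cell_meta["region"].astype(str).to_numpy()
        if "region" in cpm_matrix.cell_meta
        else np.array([""] * cpm_matrix.shape[0])
    )
    thr = {(r.gene, r.scope): r.threshold for r in table.itertuples()}
    out = {}
    for gene in panel.symbols:
        if gene not in cpm_matrix.gene_symbols or np.isnan(thr.get((gene, "combined"), np.nan)):
            continue
        col = cpm_matrix.subset_genes([gene]).to_dense().ravel()
        cutoff = np.full(col.size, thr[(gene, "combined")])
        for region in panel.region_exceptions.get(gene, ()):
            t_r = thr.get((gene, region), np.nan)
            if not np.isnan(t_r):
                cutoff[regions == region] = t_r
        out[gene] = col > cutoff
    pos = pd.DataFrame(out, index=cpm_matrix.cell_ids)
    pos.attrs["thresholds"] = table
    if "region" in cpm_matrix.cell_meta:
        pos.attrs["region"] = cpm_matrix.cell_meta["region"].astype(str)
    return pos


def coexpression_summary(
    positivity: pd.DataFrame,
    cpm_matrix: NormalizedMatrix,
    panel: HormonePanel | None = None,
    region: str | None = None,
) -> pd.DataFrame:
    """Dot-plot statistics: for each ordered hormone pair (X, Y) the number of
    X-positive cells, the fraction of them that are Y-positive, and
    log2(mean CPM of Y over X-positive cells + 1); plus a "none" row per X
    (X-positive cells positive for no other panel hormone).
    """
    if cpm_matrix.transform != "cpm":
        raise ValueError("expects the CPM matrix (the colour statistic needs mean CPM)")
    panel = panel or HormonePanel()
    genes = [g for g in panel.symbols if g in positivity.columns]
    mask = np.ones(len(positivity), dtype=bool)
    if region is not None:
        if "region" not in cpm_matrix.cell_meta:
            raise ValueError("region filter requires region labels")
        mask = cpm_matrix.cell_meta["region"].astype(str).to_numpy() == region
    pos = positivity.loc[mask, genes]
    cpm_vals = pd.DataFrame(
        cpm_matrix.subset_genes(genes).to_dense()[mask],
        columns=genes, index=pos.index,
    )
    rows = []
    for x in genes:
        xpos = pos[x].to_numpy()
        n_x = int(xpos.sum())
        others = [g for g in genes if g != x]
        for y in others:
            if n_x == 0:
                frac, colour, flagged = 0.0, np.nan, True
            else:
                frac = float(pos.loc[xpos, y].mean())
                colour = float(np.log2(cpm_vals.loc[xpos, y].mean() + 1.0))
                flagged = False
            rows.append({"region": region or "all", "x": x, "y": y, "n_x": n_x,
                         "fraction": frac, "log2_mean_cpm_y": colour,
                         "undefined": flagged})
        none_frac = (
            float((~pos.loc[xpos, others].any(axis=1)).mean()) if n_x else 0.0
        )
        rows.append({"region": region or "all", "x": x, "y": "none", "n_x": n_x,
                     "fraction": none_frac, "log2_mean_cpm_y": np.nan,
                     "undefined": n_x == 0})
    return pd.DataFrame(rows)


def venn_counts(
    positivity: pd.DataFrame,
    subset: tuple[str, ...],
    region: str | None = None,
    regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Exact membership-combination counts for <= 4 hormones (2^k - 1 rows).

    Counts sum to the number of cells positive for at least one subset gene.
    """
    if len(subset) > 4:
        raise ValueError("Venn subsets limited to 4 hormones")
    missing = [g for g in subset if g not in positivity.columns]
    if missing:
        raise KeyError(f"genes absent from positivity matrix: {missing}")
    pos = positivity[list(subset)]
    if region is not None:
        if regions is None:
            regions = positivity.attrs.get("region")
        if regions is None:
            raise ValueError("region filter requires region labels")
        pos = pos.loc[np.asarray(regions.astype(str)) == region]
    arr = pos.to_numpy(dtype=bool)
    rows = []
    for r in range(1, len(subset) + 1):
        for combo in itertools.combinations(range(len(subset)), r):
            member = np.ones(arr.shape[0], dtype=bool)
            for j in range(len(subset)):
                member &= arr[:, j] if j in combo else ~arr[:, j]
            rows.append({
                "region": region or "all",
                "combination": "+".join(subset[j] for j in combo),
                "degree": r,
                "count": int(member.sum()),
            })
    return pd.DataFrame(rows)
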