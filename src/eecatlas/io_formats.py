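"""Readers/writers for the formats the pipeline touches.

Count matrices travel as 10x-style MTX triples (MatrixMarket matrix plus
barcode and feature files, plain or gzipped) and are held in memory as
:class:`anndata.AnnData` with cells as rows.  Gene sets are plain text, one
symbol per line.  Calcium traces are CSV (time column + one ratio column per
cell) with a separate stimulus-window table.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .calcium import CalciumTrace, StimulusWindow

__all__ = [
    "GeneSet",
    "read_mtx",
    "write_mtx",
    "read_gene_set",
    "read_traces",
    "KNOWN_REGIONS",
]

KNOWN_REGIONS = ("stomach", "USI", "LSI", "caecum", "LI")


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.symbols)


def _find(dir_path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = dir_path / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {dir_path}")


def _read_table(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        try:
            return pd.read_csv(fh, sep="\t", header=None)
        except pd.errors.EmptyDataError:
            return pd.DataFrame({0: pd.Series([], dtype=str)})


def read_mtx(dir_path: str | Path) -> ad.AnnData:
    """Read an MTX triple into an AnnData of raw counts (cells x genes).

    On-disk orientation is auto-detected by matching matrix dimensions to the
    barcode and feature counts; an ambiguous square matrix is resolved as
    genes x cells (10x convention) with a warning.  Counts must be
    non-negative integers.  Cell/gene metadata CSVs written by
    :func:`write_mtx` are picked up when present.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, ("matrix.mtx",))
    bc_path = _find(dir_path, ("barcodes.tsv",))
    ft_path = _find(dir_path, ("features.tsv", "genes.tsv"))

    mat = sp.coo_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = _read_table(bc_path)[0].astype(str).tolist()
    features = _read_table(ft_path)
    symbols = features[0].astype(str).tolist()

    n_cells, n_genes = len(barcodes), len(symbols)
    if mat.shape == (n_genes, n_cells):
        if mat.shape[0] == mat.shape[1] and n_genes == n_cells:
            warnings.warn(
                f"{mtx_path.name} is square; assuming genes x cells (10x convention)"
            )
        mat = mat.T
    elif mat.shape == (n_cells, n_genes):
        pass
    else:
        raise ValueError(
            f"dimension mismatch: {mtx_path.name} is {mat.shape}, but "
            f"{bc_path.name} lists {n_cells} barcodes and {ft_path.name} "
            f"lists {n_genes} features"
        )

    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise ValueError(f"{mtx_path.name}: counts must be non-negative integers")
    counts = sp.csr_matrix(mat).astype(np.int64)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(symbols, name="gene_symbol")),
    )
    adata.var_names_make_unique()

    cm = dir_path / "cell_meta.csv"
    if cm.exists():
        meta = pd.read_csv(cm, index_col=0)
        adata.obs = adata.obs.join(meta.set_axis(adata.obs_names))
    gm = dir_path / "gene_meta.csv"
    if gm.exists():
        meta = pd.read_csv(gm, index_col=0)
        adata.var = adata.var.join(meta.set_axis(adata.var_names))
    return adata


def write_mtx(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write an AnnData of raw counts as an MTX triple (genes x cells on disk)
    plus cell/gene metadata CSVs."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    if X.data.size and np.any(X.data != np.round(X.data)):
        raise ValueError("write_mtx requires integer counts")
    scipy.io.mmwrite(
        str(dir_path / "matrix.mtx"), X.T.astype(np.int64), field="integer"
    )
    pd.Series(adata.obs_names).to_csv(
        dir_path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.var_names).to_csv(
        dir_path / "features.tsv", sep="\t", header=False, index=False
    )
    if adata.obs.shape[1]:
        adata.obs.to_csv(dir_path / "cell_meta.csv")
    if adata.var.shape[1]:
        adata.var.to_csv(dir_path / "gene_meta.csv")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set: one symbol per line, '#' comments and blanks ignored.

    Order is preserved; duplicate symbols are dropped with a warning; a file
    empty after parsing is an error.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sym = line.split("\t")[0].strip()
        if sym in seen:
            dupes.append(sym)
            continue
        seen.add(sym)
        symbols.append(sym)
    if dupes:
        warnings.warn(f"{path.name}: dropped duplicate symbols {sorted(set(dupes))}")
    if not symbols:
        raise ValueError(f"{path.name}: no gene symbols after parsing")
    return GeneSet(name=name or path.stem, symbols=tuple(symbols))


def read_traces(
    traces_path: str | Path,
    windows_path: str | Path,
    time_tolerance: float = 1e-6,
) -> list[CalciumTrace]:
    """Read calcium traces and a stimulus-window table.

    The trace CSV has a first column of time in seconds and one 340/380 ratio
    column per cell; sampling must be uniform (to ``time_tolerance``).  The
    window table (label, start_s, end_s) is mapped to half-open sample-index
    windows [start, end).
    """
    df = pd.read_csv(traces_path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace file needs at least 2 time points")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > time_tolerance:
        raise ValueError("non-uniform sampling interval")
    interval = float(dt[0])

    wdf = pd.read_csv(windows_path)
    windows = []
    for _, row in wdf.iterrows():
        start = int(round((float(row["start_s"]) - t[0]) / interval))
        end = int(round((float(row["end_s"]) - t[0]) / interval))
        windows.append(StimulusWindow(str(row["label"]), start, end))

    traces = []
    for col in df.columns[1:]:
        traces.append(
            CalciumTrace(
                cell_id=str(col),
                values=df[col].to_numpy(dtype=float),
                sampling_interval=interval,
                windows=list(windows),
            )
        )
    return traces


def write_traces(
    traces: list[CalciumTrace], traces_path: str | Path, windows_path: str | Path
) -> None:
    """Inverse of :func:`read_traces` (shared window table, uniform sampling)."""
    if not traces:
        raise ValueError("no traces to write")
    interval = traces[0].sampling_interval
    n = len(traces[0])
    data = {"time_s": np.arange(n) * interval}
    for tr in traces:
        if len(tr) != n or tr.sampling_interval != interval:
            raise ValueError("traces must share length and sampling interval")
        data[tr.cell_id] = tr.values
    pd.DataFrame(data).to_csv(traces_path, index=False)
    wrows = [
        {"label": w.label, "start_s": w.start * interval, "end_s": w.end * interval}
        for w in traces[0].windows
    ]
    pd.DataFrame(wrows, columns=["label", "start_s", "end_s"]).to_csv(
        windows_path, index=False
    )
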