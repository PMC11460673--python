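"""Synthetic data with known ground truth for the atlas pipeline.

Two generators:

* :func:`generate_counts` — multi-region negative-binomial count matrices with
  planted cell types, bimodally expressed hormone genes ("on" in the planted
  type, ambient elsewhere), a curated set of signalling-pathway program genes,
  flat background genes, per-cell library-size variation (log-normal),
  per-cell mitochondrial read fractions (Beta), and per-region multiplicative
  batch shifts.
* :func:`generate_traces` — fura-2 340/380 ratio time series sampled every
  2 s, with planted responder transients (linear 5-sample rise, exponential
  decay) inside declared stimulus windows.

Counts are drawn NB(mean, size) with mean = libsize x CPM / 1e6 x region
shift, so empirical moments follow var = mu + mu^2/size.  Background gene
CPMs are rescaled per cell type so expected total CPM is 1e6, which makes the
drawn library size the expected total count.  Mitochondrial gene means are
calibrated per cell so the expected mitochondrial fraction equals the Beta
draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .calcium import CalciumTrace, StimulusWindow

__all__ = [
    "SyntheticAtlasSpec",
    "AtlasGroundTruth",
    "SyntheticTraceSpec",
    "generate_counts",
    "generate_traces",
    "example_atlas_spec",
]

MITO_GENES = ("mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Cytb", "mt-Atp6")
_MITO_WEIGHTS = np.array([0.30, 0.15, 0.25, 0.18, 0.12])
#: treat NB size above this as the Poisson limit when sampling
_POISSON_SIZE = 1e6


@dataclass
class SyntheticAtlasSpec:
    """Ground-truth description of a multi-region synthetic EEC atlas.

    ``hormone_programs`` and ``gpcr_programs`` are (gene x cell type) tables
    of NB mean CPM.  A hormone entry > 0 marks the type as "on" for that
    hormone; off-state cells express it at ``ambient_cpm`` (overridable per
    (gene, region) via ``ambient_overrides``, emulating e.g. high gastric
    Sst/Ghrl background).
    """

    regions: list[str]
    cell_types: list[tuple[str, int]]  # (name, n cells per region)
    hormone_programs: pd.DataFrame
    gpcr_programs: pd.DataFrame
    n_background_genes: int = 200
    #: NB size, shared across genes; 10 is typical for abundantly expressed
    #: genes in UMI data and keeps bimodal hormone modes separable, which the
    #: positivity-recovery guarantees of the threshold module presuppose
    dispersion: float = 10.0
    libsize_lognormal: tuple[float, float] = (np.log(10_000.0), 0.5)
    mito_fraction_beta: tuple[float, float] = (2.0, 25.0)
    batch_shift_sd: float = 0.15
    ambient_cpm: float = 2.0
    ambient_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types or sum(n for _, n in self.cell_types) == 0:
            raise ValueError("no cells requested")
        if any(n < 0 for _, n in self.cell_types):
            raise ValueError("cell counts must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for tbl, what in ((self.hormone_programs, "hormone"), (self.gpcr_programs, "gpcr")):
            if tbl.size and (tbl.to_numpy() < 0).any():
                raise ValueError(f"negative {what} program mean")
        if self.ambient_cpm < 0 or self.n_background_genes < 0:
            raise ValueError("ambient_cpm and n_background_genes must be >= 0")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ValueError("mito_fraction_beta parameters must be > 0")
        type_names = [t for t, _ in self.cell_types]
        for tbl in (self.hormone_programs, self.gpcr_programs):
            missing = set(tbl.columns) - set(type_names)
            if missing:
                raise ValueError(f"program table references unknown cell types {missing}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticAtlasSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cfg["cell_types"] = [tuple(x) for x in cfg["cell_types"]]
        cfg["hormone_programs"] = pd.DataFrame(cfg["hormone_programs"])
        cfg["gpcr_programs"] = pd.DataFrame(cfg.get("gpcr_programs", {}))
        cfg["ambient_overrides"] = {
            (g, r): v for g, r, v in cfg.get("ambient_overrides", [])
        }
        cfg["libsize_lognormal"] = tuple(cfg.get("libsize_lognormal", (np.log(1e4), 0.5)))
        cfg["mito_fraction_beta"] = tuple(cfg.get("mito_fraction_beta", (2.0, 25.0)))
        return cls(**cfg)


@dataclass
class AtlasGroundTruth:
    """Per-cell planted truth aligned with the generated matrix."""

    cell_type: pd.Series        # planted type label per cell
    region: pd.Series
    hormone_on: pd.DataFrame    # bool, cells x hormone genes


@dataclass
class SyntheticTraceSpec:
    """Planted-truth description of a fura-2 trace cohort.

    ``stimuli`` entries are (label, start index, end index, amplitude
    distribution); amplitude distributions are ("fixed", a),
    ("normal", mu, sd) (truncated at 0) or ("lognormal", mu, sigma).
    ``responder_matrix`` is the boolean cells x stimuli truth.
    """

    n_cells: int
    n_timepoints: int
    stimuli: list[tuple[str, int, int, tuple]]
    responder_matrix: np.ndarray
    sampling_interval: float = 2.0
    baseline_ratio: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0
    rise_samples: int = 5
    decay_tau: float = 10.0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_timepoints <= 0:
            raise ValueError("n_cells and n_timepoints must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")
        mat = np.asarray(self.responder_matrix, dtype=bool)
        if mat.shape != (self.n_cells, len(self.stimuli)):
            raise ValueError("responder_matrix must be n_cells x n_stimuli")
        spans = sorted((s, e, l) for l, s, e, _ in self.stimuli)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"stimulus windows {l1!r} and {l2!r} overlap")
        for l, s, e, _ in self.stimuli:
            if s < 10:
                raise ValueError(f"window {l!r} needs >= 10 preceding samples")
            if e > self.n_timepoints or e <= s:
                raise ValueError(f"window {l!r} outside trace")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """NB(mean, size) draws; Poisson limit for very large size."""
    mean = np.asarray(mean, dtype=float)
    if size >= _POISSON_SIZE:
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(spec: SyntheticAtlasSpec) -> tuple[ad.AnnData, AtlasGroundTruth]:
    """Draw a multi-region count matrix plus its planted ground truth.

    Fully reproducible from ``spec.seed``; cells are emitted region-major,
    then type-major, in the order the spec lists them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    hormones = list(spec.hormone_programs.index)
    gpcrs = list(spec.gpcr_programs.index)
    n_bg = spec.n_background_genes
    bg_genes = [f"Bg{i:04d}" for i in range(n_bg)]
    genes = hormones + gpcrs + bg_genes
    n_genes = len(genes)

    # flat background profile, rescaled per type so total expected CPM = 1e6
    bg_base = rng.lognormal(0.0, 1.0, n_bg)
    bg_base = bg_base / bg_base.sum() if n_bg else bg_base

    type_names = [t for t, _ in spec.cell_types]
    hp = spec.hormone_programs.reindex(columns=type_names, fill_value=0.0)
    gp = spec.gpcr_programs.reindex(columns=type_names, fill_value=0.0)
    cpm_by_type: dict[str, np.ndarray] = {}
    for t in type_names:
        vec = np.empty(n_genes)
        for i, g in enumerate(hormones):
            on = hp.loc[g, t]
            vec[i] = on if on > 0 else spec.ambient_cpm
        for i, g in enumerate(gpcrs):
            vec[len(hormones) + i] = gp.loc[g, t]
        fixed = vec[: len(hormones) + len(gpcrs)].sum()
        if n_bg:
            bg_total = max(1e6 - fixed, 0.0)
            if bg_total == 0.0:
                warnings.warn(f"type {t!r}: program CPM exceeds 1e6; no background mass")
            vec[len(hormones) + len(gpcrs):] = bg_base * bg_total
        cpm_by_type[t] = vec

    # per-region multiplicative log-normal gene shifts (shared across types)
    shifts = {
        r: rng.lognormal(0.0, spec.batch_shift_sd, n_genes) if spec.batch_shift_sd > 0
        else np.ones(n_genes)
        for r in spec.regions
    }

    meanlog, sdlog = spec.libsize_lognormal
    a_mito, b_mito = spec.mito_fraction_beta

    blocks, cell_ids, regions_out, types_out = [], [], [], []
    idx = 0
    for region in spec.regions:
        for t, n in spec.cell_types:
            if n == 0:
                continue
            cpm = cpm_by_type[t].copy()
            for i, g in enumerate(hormones):
                if hp.loc[g, t] <= 0 and (g, region) in spec.ambient_overrides:
                    cpm[i] = spec.ambient_overrides[(g, region)]
            libsize = rng.lognormal(meanlog, sdlog, n)
            mito_frac = rng.beta(a_mito, b_mito, n)
            means = libsize[:, None] * (cpm * shifts[region])[None, :] / 1e6
            mito_total = mito_frac / (1.0 - mito_frac) * means.sum(axis=1)
            mito_means = mito_total[:, None] * _MITO_WEIGHTS[None, :]
            counts = _nb_sample(rng, np.hstack([means, mito_means]), spec.dispersion)
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            cell_ids.extend(f"{region}-{idx + i:05d}" for i in range(n))
            idx += n
            regions_out.extend([region] * n)
            types_out.extend([t] * n)

    X = sp.vstack(blocks, format="csr")
    all_genes = genes + list(MITO_GENES)
    obs = pd.DataFrame(
        {"region": pd.Categorical(regions_out, categories=spec.regions)},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {"mito": [g.lower().startswith("mt-") for g in all_genes]},
        index=pd.Index(all_genes, name="gene_symbol"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)

    hormone_on = pd.DataFrame(
        {g: [hp.loc[g, t] > 0 for t in types_out] for g in hormones},
        index=adata.obs_names,
    )
    truth = AtlasGroundTruth(
        cell_type=pd.Series(types_out, index=adata.obs_names, name="cell_type"),
        region=pd.Series(regions_out, index=adata.obs_names, name="region"),
        hormone_on=hormone_on,
    )
    return adata, truth


def _draw_amplitude(rng: np.random.Generator, dist: tuple) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "normal":
        return float(max(rng.normal(dist[1], dist[2]), 0.0))
    if kind == "lognormal":
        return float(rng.lognormal(dist[1], dist[2]))
    raise ValueError(f"unknown amplitude distribution {kind!r}")


def _transient(n: int, start: int, amplitude: float, rise: int, tau: float) -> np.ndarray:
    """Linear rise over ``rise`` samples to ``amplitude``, then exp decay."""
    out = np.zeros(n)
    t = np.arange(start, n)
    ramp = np.minimum((t - start + 1) / rise, 1.0) * amplitude
    decay = amplitude * np.exp(-(t - (start + rise - 1)) / tau)
    out[start:] = np.where(t - start < rise, ramp, decay)
    return out


def generate_traces(
    spec: SyntheticTraceSpec,
) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Draw a cohort of fura-2 traces plus the planted responder truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    windows = [StimulusWindow(l, s, e) for l, s, e, _ in spec.stimuli]
    truth = pd.DataFrame(
        np.asarray(spec.responder_matrix, dtype=bool),
        index=[f"cell{i:04d}" for i in range(spec.n_cells)],
        columns=[w.label for w in windows],
    )

    traces = []
    for i in range(spec.n_cells):
        vals = spec.baseline_ratio + (
            rng.normal(0.0, spec.noise_sd, spec.n_timepoints)
            if spec.noise_sd > 0
            else np.zeros(spec.n_timepoints)
        )
        for j, (label, start, end, dist) in enumerate(spec.stimuli):
            if truth.iloc[i, j]:
                amp = _draw_amplitude(rng, dist)
                if amp == 0.0:  # degenerate draw: nothing planted, truth corrected
                    truth.iloc[i, j] = False
                    continue
                vals += _transient(
                    spec.n_timepoints, start, amp, spec.rise_samples, spec.decay_tau
                )
        traces.append(
            CalciumTrace(
                cell_id=truth.index[i],
                values=vals,
                sampling_interval=spec.sampling_interval,
                windows=list(windows),
            )
        )
    return traces, truth


# ---------------------------------------------------------------------------
# study-condition defaults

#: planted hormone -> cell type map used by the example atlas (L co-expresses
#: Gcg and Pyy, giving a known pairwise overlap)
_EXAMPLE_PROGRAMS = {
    "Sst": {"D": 3000.0},
    "Cck": {"I": 2500.0},
    "Gip": {"K": 2500.0},
    "Gcg": {"L": 3000.0},
    "Pyy": {"L": 2500.0},
    "Nts": {"N": 2000.0},
    "Sct": {"S": 2000.0},
    "Ghrl": {"X": 3000.0},
}

_EXAMPLE_GPCR_PROGRAMS = {
    "D": ("Casr", "Adcy5", "Kcnq1"),
    "I": ("Ffar1", "Gpr119", "Itpr1"),
    "K": ("Ffar4", "Adcy8", "Trpm5"),
    "L": ("Gpbar1", "Plcb1", "Ryr2"),
    "N": ("Gper1", "Prkca", "Cacna1c"),
    "S": ("Adcy6", "Prkacb", "Kcnj3"),
    "X": ("Gpr142", "Pde4b", "Stim1"),
}


def example_atlas_spec(n_per_type: int = 25, seed: int = 0) -> SyntheticAtlasSpec:
    """Five-region, seven-type atlas spec mirroring the structure the analysis
    assumes: one dominant hormone per type (L co-expressing Gcg and Pyy at
    twice the per-type cell count), three enriched signalling genes plus ten
    strong marker-program genes per type (each real EEC subtype carries on
    the order of ten distinctive genes beyond its hormone), and high gastric
    ambient Sst/Ghrl.
    """
    types = ["D", "I", "K", "L", "N", "S", "X"]
    programs = pd.DataFrame(0.0, index=list(_EXAMPLE_PROGRAMS), columns=types)
    for g, d in _EXAMPLE_PROGRAMS.items():
        for t, v in d.items():
            programs.loc[g, t] = v
    gpcr_genes = sorted({g for gs in _EXAMPLE_GPCR_PROGRAMS.values() for g in gs})
    marker_genes = [f"{t}mk{i:02d}" for t in types for i in range(10)]
    gpcr = pd.DataFrame(15.0, index=gpcr_genes + marker_genes, columns=types)
    for t, gs in _EXAMPLE_GPCR_PROGRAMS.items():
        for g in gs:
            gpcr.loc[g, t] = 300.0
    for t in types:
        gpcr.loc[[f"{t}mk{i:02d}" for i in range(10)], :] = 4.0
        gpcr.loc[[f"{t}mk{i:02d}" for i in range(10)], t] = 1000.0
    cell_types = [(t, n_per_type if t != "L" else 2 * n_per_type) for t in types]
    return SyntheticAtlasSpec(
        regions=["stomach", "USI", "LSI", "caecum", "LI"],
        cell_types=cell_types,
        hormone_programs=programs,
        gpcr_programs=gpcr,
        n_background_genes=200,
        ambient_overrides={("Sst", "stomach"): 60.0, ("Ghrl", "stomach"): 60.0},
        seed=seed,
    )
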