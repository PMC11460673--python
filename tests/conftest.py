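"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written as plain loops / grid searches so
they stay independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eecatlas import synthetic_data as sd


# ---------------------------------------------------------------------------
# oracles


def huang_oracle(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive fuzzy-entropy scan over every candidate bin cut."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    h, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    C = hi - lo
    best_e, best_t = math.inf, None
    for t in range(n_bins):
        n0 = h[: t + 1].sum()
        n1 = h[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = float((h[: t + 1] * centers[: t + 1]).sum() / n0)
        mu1 = float((h[t + 1 :] * centers[t + 1 :]).sum() / n1)
        e = 0.0
        for b in range(n_bins):
            if h[b] == 0:
                continue
            mu = mu0 if b <= t else mu1
            u = 1.0 / (1.0 + abs(centers[b] - mu) / C)
            if 0.0 < u < 1.0:
                e += h[b] * (-u * math.log(u) - (1.0 - u) * math.log(1.0 - u))
        if e < best_e:
            best_e, best_t = e, t
    return float(edges[best_t + 1])


def nb_loglik(y, mu, alpha):
    """NB log-likelihood, var = mu + alpha mu^2."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def nb_lrt_oracle(y, indicator, offset, alpha) -> float:
    """Grid-search LRT statistic for count ~ b0 (+ b1*indicator) + offset.

    Three rounds of grid refinement around the running optimum; independent
    of the IRLS fitting route.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(indicator, dtype=float)
    off = np.asarray(offset, dtype=float)

    def maximize(use_slope: bool) -> float:
        b0, b1 = 0.0, 0.0
        half0, half1 = 8.0, 8.0
        best = -math.inf
        for _ in range(6):
            b0_grid = np.linspace(b0 - half0, b0 + half0, 41)
            b1_grid = np.linspace(b1 - half1, b1 + half1, 41) if use_slope else [0.0]
            for c0 in b0_grid:
                for c1 in b1_grid:
                    mu = np.exp(c0 + c1 * x + off)
                    ll = nb_loglik(y, mu, alpha)
                    if ll > best:
                        best, b0_best, b1_best = ll, c0, c1
            b0, b1 = b0_best, b1_best
            half0 /= 10.0
            half1 /= 10.0
        return best

    return 2.0 * (maximize(True) - maximize(False))


@pytest.fixture(scope="session")
def oracles():
    return {"huang": huang_oracle, "nb_lrt": nb_lrt_oracle, "nb_loglik": nb_loglik}


# ---------------------------------------------------------------------------
# synthetic fixtures


@pytest.fixture(scope="session")
def small_atlas():
    """5-region, 7-type atlas (20 cells per type, 40 for L) with truth."""
    spec = sd.example_atlas_spec(n_per_type=20, seed=11)
    adata, truth = sd.generate_counts(spec)
    return spec, adata, truth


@pytest.fixture(scope="session")
def single_region_atlas():
    """2000-cell single-region, 5-type atlas for clustering checks."""
    types = ["D", "I", "K", "L", "N"]
    prog = pd.DataFrame(
        0.0, index=["Sst", "Cck", "Gip", "Gcg", "Pyy", "Nts"], columns=types
    )
    prog.loc["Sst", "D"] = 3000
    prog.loc["Cck", "I"] = 2500
    prog.loc["Gip", "K"] = 2500
    prog.loc["Gcg", "L"] = 3000
    prog.loc["Pyy", "L"] = 2500
    prog.loc["Nts", "N"] = 2000
    gpcr = sd.example_atlas_spec().gpcr_programs[types]
    spec = sd.SyntheticAtlasSpec(
        regions=["USI"],
        cell_types=[(t, 400) for t in types],
        hormone_programs=prog,
        gpcr_programs=gpcr,
        seed=7,
    )
    adata, truth = sd.generate_counts(spec)
    return spec, adata, truth
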