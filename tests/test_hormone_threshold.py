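"""Huang thresholding against a brute-force oracle; positivity bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from eecatlas import hormone_threshold as ht
from eecatlas import normalize as nz
from eecatlas.pipeline import run_positivity


def _random_histogram_sample(rng):
    """Mixture of a point mass at 0 and NB draws, like a hormone CPM column."""
    n = rng.integers(100, 400)
    frac_on = rng.uniform(0.1, 0.6)
    n_on = max(int(n * frac_on), 2)
    mean = rng.uniform(50, 5000)
    size = rng.uniform(0.5, 5)
    on = rng.negative_binomial(size, size / (size + mean), n_on).astype(float)
    off = np.zeros(n - n_on)
    values = np.concatenate([on, off])
    if values.min() == values.max():
        values[0] += 1.0
    return values


def test_huang_matches_bruteforce_oracle(oracles):
    """Exact agreement with the exhaustive fuzzy-entropy scan on 25 mixtures."""
    for seed in range(25):
        rng = np.random.default_rng(seed)
        values = _random_histogram_sample(rng)
        assert ht.huang_threshold(values) == oracles["huang"](values), f"seed {seed}"


def test_two_mass_threshold_separates_modes(oracles):
    values = np.concatenate([np.zeros(60), np.full(40, 1000.0)])
    thr = ht.huang_threshold(values)
    assert 0 < thr < 1000
    assert thr == oracles["huang"](values)


def test_scale_equivariance():
    rng = np.random.default_rng(5)
    values = _random_histogram_sample(rng)
    a = 7.3
    bin_w = (values.max() - values.min()) / 256
    assert ht.huang_threshold(a * values) == pytest.approx(
        a * ht.huang_threshold(values), abs=a * bin_w * 1.01
    )


def test_mirror_symmetry():
    rng = np.random.default_rng(6)
    values = _random_histogram_sample(rng)
    hi = values.max()
    bin_w = (hi - values.min()) / 256
    assert ht.huang_threshold(hi - values) == pytest.approx(
        hi - ht.huang_threshold(values), abs=2 * bin_w
    )


def test_degenerate_distribution_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        ht.huang_threshold(np.full(10, 3.0))


def _cpm_nm(values, regions=None, genes=None):
    values = np.asarray(values, dtype=float)
    meta = pd.DataFrame(index=[f"c{i}" for i in range(values.shape[0])])
    if regions is not None:
        meta["region"] = regions
    return nz.NormalizedMatrix(
        values=values,
        cell_ids=meta.index,
        gene_symbols=pd.Index(genes or [f"g{i}" for i in range(values.shape[1])]),
        transform="cpm",
        cell_meta=meta,
    )


def test_threshold_table_scopes(small_atlas):
    """Sst/Ghrl get combined + stomach entries; other hormones combined only."""
    _, adata, _ = small_atlas
    with pytest.warns(UserWarning, match="absent"):
        table, pos = run_positivity(adata)
    assert set(table.loc[table.gene == "Sst", "scope"]) == {"combined", "stomach"}
    assert list(table.loc[table.gene == "Gcg", "scope"]) == ["combined"]
    # stomach-scoped thresholds sit above the combined ones (high gastric ambient)
    sst = table.set_index(["gene", "scope"])["threshold"]
    assert sst[("Sst", "stomach")] > 0
    assert pos.dtypes.unique().tolist() == [np.dtype(bool)]


def test_positivity_strict_inequality():
    rng = np.random.default_rng(0)
    col = np.concatenate([np.zeros(50), rng.uniform(900, 1100, 50)])
    m = _cpm_nm(col[:, None], genes=["Gcg"])
    panel = ht.HormonePanel(symbols=("Gcg",), region_exceptions={})
    table = ht.build_threshold_table(m, panel)
    thr = float(table.threshold.iloc[0])
    m_exact = _cpm_nm(np.array([[thr], [thr + 1e-9]]), genes=["Gcg"])
    pos = ht.call_positive(m_exact, table, panel)
    assert not pos["Gcg"].iloc[0]      # CPM == threshold -> negative
    assert pos["Gcg"].iloc[1]


def test_region_scoped_threshold_applies_only_in_region():
    rng = np.random.default_rng(1)
    # stomach: high ambient; elsewhere clean on/off
    regions = ["stomach"] * 100 + ["USI"] * 100
    col = np.concatenate([
        rng.uniform(100, 300, 50), rng.uniform(2000, 3000, 50),  # stomach
        np.zeros(50), rng.uniform(2000, 3000, 50),               # USI
    ])
    m = _cpm_nm(col[:, None], regions=regions, genes=["Sst"])
    panel = ht.HormonePanel(symbols=("Sst",), region_exceptions={"Sst": ("stomach",)})
    table = ht.build_threshold_table(m, panel)
    pos = ht.call_positive(m, table, panel)
    thr = table.set_index("scope")["threshold"]
    # stomach cells judged against the stomach threshold, USI against combined
    stomach_pos = pos["Sst"].to_numpy()[:100]
    np.testing.assert_array_equal(stomach_pos, col[:100] > thr["stomach"])
    usi_pos = pos["Sst"].to_numpy()[100:]
    np.testing.assert_array_equal(usi_pos, col[100:] > thr["combined"])


def test_all_zero_gene_never_positive():
    m = _cpm_nm(np.zeros((10, 1)), genes=["Gcg"])
    panel = ht.HormonePanel(symbols=("Gcg",), region_exceptions={})
    with pytest.warns(UserWarning, match="degenerate"):
        table = ht.build_threshold_table(m, panel)
    pos = ht.call_positive(m, table, panel)
    assert pos.empty or not pos.get("Gcg", pd.Series(dtype=bool)).any()


def _toy_positivity():
    # 6 cells: X+ = {0,1,2,3}, Y+ = {2,3,4}
    pos = pd.DataFrame(
        {"X": [1, 1, 1, 1, 0, 0], "Y": [0, 0, 1, 1, 1, 0]}, dtype=bool,
        index=[f"c{i}" for i in range(6)],
    )
    cpmv = _cpm_nm(np.ones((6, 2)) * 100.0, genes=["X", "Y"])
    return pos, cpmv


def test_coexpression_hand_count():
    pos, cpmv = _toy_positivity()
    panel = ht.HormonePanel(symbols=("X", "Y"), region_exceptions={})
    summ = ht.coexpression_summary(pos, cpmv, panel)
    row = summ[(summ.x == "X") & (summ.y == "Y")].iloc[0]
    assert row.n_x == 4 and row.fraction == pytest.approx(0.5)
    none_row = summ[(summ.x == "X") & (summ.y == "none")].iloc[0]
    assert none_row.fraction == pytest.approx(0.5)


def test_coexpression_intersection_symmetry(small_atlas):
    """fraction(X->Y) n(X) = fraction(Y->X) n(Y) = |X n Y|."""
    _, adata, _ = small_atlas
    with pytest.warns(UserWarning):
        _, pos = run_positivity(adata)
    cpmv = nz.cpm(adata)
    genes = tuple(pos.columns)
    panel = ht.HormonePanel(symbols=genes, region_exceptions={})
    summ = ht.coexpression_summary(pos, cpmv, panel).set_index(["x", "y"])
    for x, y in [("Gcg", "Pyy"), ("Cck", "Sst")]:
        nx = summ.loc[(x, y), "n_x"]
        ny = summ.loc[(y, x), "n_x"]
        inter = int((pos[x] & pos[y]).sum())
        assert round(summ.loc[(x, y), "fraction"] * nx) == inter
        assert round(summ.loc[(y, x), "fraction"] * ny) == inter


def test_zero_positive_cells_flagged():
    pos, cpmv = _toy_positivity()
    pos["X"] = False
    panel = ht.HormonePanel(symbols=("X", "Y"), region_exceptions={})
    summ = ht.coexpression_summary(pos, cpmv, panel)
    row = summ[(summ.x == "X") & (summ.y == "Y")].iloc[0]
    assert row.n_x == 0 and row.fraction == 0.0 and row.undefined


def test_venn_trivial_cases():
    idx = [f"c{i}" for i in range(6)]
    disjoint = pd.DataFrame(
        {"A": [1, 1, 0, 0, 0, 0], "B": [0, 0, 1, 1, 0, 0]}, dtype=bool, index=idx
    )
    v = ht.venn_counts(disjoint, ("A", "B")).set_index("combination")["count"]
    assert v["A"] == 2 and v["B"] == 2 and v["A+B"] == 0

    full = pd.DataFrame(np.ones((4, 4), dtype=bool), columns=list("ABCD"))
    v = ht.venn_counts(full, ("A", "B", "C", "D"))
    assert v.loc[v.combination == "A+B+C+D", "count"].iloc[0] == 4
    assert v[v.combination != "A+B+C+D"]["count"].sum() == 0


def test_venn_reconciles_with_column_sums(small_atlas):
    _, adata, _ = small_atlas
    with pytest.warns(UserWarning):
        _, pos = run_positivity(adata)
    subset = ("Gcg", "Cck", "Sct", "Pyy")
    v = ht.venn_counts(pos, subset)
    # total count equals cells positive for >= 1 subset gene
    assert v["count"].sum() == int(pos[list(subset)].any(axis=1).sum())
    # per-gene sum over combinations containing the gene equals its column sum
    for g in subset:
        total = v.loc[v.combination.str.split("+").map(lambda c: g in c), "count"].sum()
        assert total == int(pos[g].sum())


def test_venn_subset_size_limited():
    pos = pd.DataFrame(np.zeros((2, 5), dtype=bool), columns=list("ABCDE"))
    with pytest.raises(ValueError, match="4"):
        ht.venn_counts(pos, ("A", "B", "C", "D", "E"))
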