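#!/usr/bin/env python
"""Integrate the per-region datasets with the simplified CCA embedding.

Selects 2000-capped integration features (union of per-region variable
genes), scales each region on the shared features, merges all regions onto
the largest by cross-product SVD, and checks that planted cell types — not
regions — dominate the joint canonical space.
"""

import warnings
from pathlib import Path

import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from eecatlas import integrate as ig, qc, synthetic_data as sd
from eecatlas.normalize import cpm, log_norm, scale_genes

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = sd.example_atlas_spec(n_per_type=125, seed=SEED)
    adata, truth = sd.generate_counts(spec)
    regions = qc.split_by_region(adata)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = ig.integration_features(list(regions.values()), n=2000)
        datasets = {
            r: scale_genes(log_norm(cpm(sub[:, list(feats.symbols)].copy())))
            for r, sub in regions.items()
        }
        res = ig.integrate_all(datasets, n_cc=20, features=feats.symbols)

    labels = KMeans(n_clusters=7, n_init=10, random_state=SEED).fit_predict(res.embedding)
    truth_types = truth.cell_type[res.cell_ids]
    ari_types = adjusted_rand_score(truth_types, labels)
    ari_region = adjusted_rand_score(res.dataset_of_origin, labels)
    print(f"integration features: {len(feats)} (union of per-region variable genes)")
    print(f"merge order (largest first): {res.merge_order}")
    print(f"joint-embedding k-means ARI vs planted cell types: {ari_types:.3f}")
    print(f"joint-embedding k-means ARI vs region of origin:  {ari_region:.3f}")
    print("cell types, not regions, organize the canonical space"
          if ari_types > ari_region else "warning: regions dominate the embedding")

    pd.DataFrame({
        "metric": ["n_features", "ari_vs_types", "ari_vs_region"],
        "value": [len(feats), ari_types, ari_region],
    }).to_csv(RESULTS / "integration_summary.csv", index=False)


if __name__ == "__main__":
    main()
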