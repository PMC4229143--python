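#!/usr/bin/env python
"""Genotype preparation: imputation, structure PCA, MAF filtering.

Imputes missing calls by marker means, computes the first two principal
components of the full imputed marker set (used later to residualize the
traits), checks how well k-means on those PCs recovers the simulated
ancestry clusters, and removes markers with MAF < 0.05 among the
phenotyped genotypes.

Writes results/genotypes/{pc_scores.csv, genotypes_filtered.tsv,
structure_summary.json}.
"""

import json
from itertools import permutations
from pathlib import Path

import numpy as np
from scipy.cluster.vq import kmeans2

from switchgs.snp import (filter_maf, impute_missing, pca_scores,
                          read_snp_matrix, write_pc_scores, write_snp_matrix)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20140112


def main() -> None:
    matrix = read_snp_matrix(ROOT / "panel" / "genotypes.tsv", "tabular")
    truth = json.loads((ROOT / "panel" / "sim_truth.json").read_text())
    out = ROOT / "genotypes"
    out.mkdir(parents=True, exist_ok=True)

    imputed = impute_missing(matrix, "marker_mean", rng_seed=SEED)
    pcs = pca_scores(imputed, k=2)
    write_pc_scores(pcs, out / "pc_scores.csv")

    cluster_of = truth["cluster_of_population"]
    labels = np.array([cluster_of[s.split("_")[0]] for s in matrix.samples])
    _, assign = kmeans2(pcs.scores, 3, seed=SEED, minit="++")
    agree = max(
        float(np.mean(np.array([p[a] for a in assign]) == labels))
        for p in permutations(range(3))
    )

    filtered = filter_maf(imputed, 0.05)
    write_snp_matrix(filtered, out / "genotypes_filtered.tsv")

    summary = {
        "n_markers_total": matrix.n_markers,
        "n_markers_after_maf": filtered.n_markers,
        "missing_call_fraction": round(float(matrix.missing_mask.mean()), 4),
        "pc1_pc2_explained_variance": [round(float(v), 4)
                                       for v in pcs.explained_variance],
        "kmeans_cluster_agreement": round(agree, 4),
    }
    (out / "structure_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
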