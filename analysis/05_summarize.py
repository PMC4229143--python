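#!/usr/bin/env python
"""Cross-trait summary: does repeatability track prediction accuracy?

Computes the Spearman rank correlation between the estimated clone-mean
repeatabilities and the unstandardized mean fold correlations (per model
and averaged over models), and draws the PC scatter and accuracy bar
chart.

Writes results/summary/{spearman.json, pc_scatter.png, accuracy_bars.png}.
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from switchgs.cv import repeatability_accuracy_spearman

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "summary"
    out.mkdir(parents=True, exist_ok=True)
    cv = pd.read_csv(ROOT / "cv" / "cv_report.csv")
    meta = json.loads((ROOT / "phenotypes" / "blup_meta.json").read_text())
    h = {t: meta[t]["repeatability"] for t in cv["trait"].unique()}

    spearman = {}
    for model, grp in cv.groupby("model"):
        raw = dict(zip(grp["trait"], grp["mean_r"]))
        spearman[model] = repeatability_accuracy_spearman(h, raw)
    raw_avg = cv.groupby("trait")["mean_r"].mean().to_dict()
    spearman["mean_over_models"] = repeatability_accuracy_spearman(h, raw_avg)
    (out / "spearman.json").write_text(json.dumps(spearman, indent=2))
    print("Spearman(repeatability, unstandardized mean r):")
    for k, v in spearman.items():
        print(f"  {k:16s} {v:+.3f}")

    pcs = pd.read_csv(ROOT / "genotypes" / "pc_scores.csv")
    truth = json.loads((ROOT / "panel" / "sim_truth.json").read_text())
    cluster = pcs["sample_id"].str.split("_").str[0].map(
        truth["cluster_of_population"])
    fig, ax = plt.subplots(figsize=(5, 4))
    for c, grp in pcs.groupby(cluster):
        ax.scatter(grp["PC1"], grp["PC2"], s=6, alpha=0.6, label=f"cluster {c}")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pc_scatter.png", dpi=120)

    summary = pd.read_csv(ROOT / "cv" / "summary.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    summary.drop(columns="mean").plot.bar(ax=ax)
    ax.set_ylabel("standardized accuracy")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(out / "accuracy_bars.png", dpi=120)
    print(f"figures -> {out}")


if __name__ == "__main__":
    main()
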