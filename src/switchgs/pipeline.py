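"""End-to-end run orchestration: config validation, staged execution,
reports, and a reproducibility manifest.

Stages: obtain data (simulate or load) -> phenotype preparation (outlier
screen, BLUPs, repeatability, Box-Cox) -> genotype preparation (impute,
PCA on the full marker set, MAF filter) -> PC residualization ->
population-grouped cross-validation of each model -> summary tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cv import (CvReport, cross_validate, make_group_folds, report_table,
                 residualize_on_pcs)
from .models import MODELS
from .phenotypes import TraitSummary, blup_table, prepare_trait, validate_trial_table
from .simulate import SimConfig, simulate_panel
from .snp import (SnpMatrix, filter_maf, impute_missing, pca_scores,
                  read_snp_matrix, write_pc_scores, write_snp_matrix)

log = logging.getLogger("switchgs")


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    out_dir: Path
    traits: list[str]
    models: list[str] = field(default_factory=lambda: list(MODELS))
    alpha: float = 0.5  # elastic-net mixing; LASSO and ridge are the endpoints
    k_folds: int = 10
    k_pcs: int = 2
    maf_threshold: float = 0.05
    imputation: str = "marker_mean"
    outlier_cutoff: float = 4.0
    boxcox: bool = True
    inner_folds: int = 5
    seed: int = 0
    simulate: SimConfig | None = None
    genotype_path: Path | None = None
    genotype_format: str = "tabular"
    phenotype_path: Path | None = None
    use_transformed_blups: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        for k in ("genotype_path", "phenotype_path"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


_KNOWN_KEYS = {
    "out_dir", "traits", "models", "alpha", "k_folds", "k_pcs",
    "maf_threshold", "imputation", "outlier_cutoff", "boxcox",
    "inner_folds", "seed", "simulate", "inputs", "use_transformed_blups",
}

_DEFAULTS_LOGGED = (
    ("k_folds", 10), ("k_pcs", 2), ("alpha", 0.5), ("maf_threshold", 0.05),
    ("outlier_cutoff", 4.0), ("imputation", "marker_mean"), ("inner_folds", 5),
)


def validate_config(path: str | Path) -> RunConfig:
    """Load and schema-check a YAML run config; all problems reported
    together. Every default that fills a gap is logged."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    traits = raw.get("traits") or []
    if not traits:
        errors.append("traits: at least one trait required")
    if len(set(traits)) != len(traits):
        errors.append("traits: duplicate names")
    models = raw.get("models", list(MODELS))
    bad = [m for m in models if m not in MODELS]
    if bad:
        errors.append(f"models: unknown {bad}; choose from {MODELS}")
    if not models:
        errors.append("models: list must be non-empty")
    alpha = raw.get("alpha", 0.5)
    if not 0.0 <= alpha <= 1.0:
        errors.append(f"alpha: {alpha} outside [0, 1]")
    maf = raw.get("maf_threshold", 0.05)
    if not 0.0 <= maf <= 0.5:
        errors.append(f"maf_threshold: {maf} outside [0, 0.5]")
    if raw.get("imputation", "marker_mean") not in ("marker_mean", "marker_mode", "knn"):
        errors.append(f"imputation: unknown method {raw.get('imputation')!r}")

    sim_cfg = None
    geno = pheno = None
    if "simulate" in raw:
        try:
            sim_cfg = SimConfig(**{**raw["simulate"], "rng_seed": raw.get("seed", 0)})
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    elif "inputs" in raw:
        inputs = raw["inputs"]
        geno = Path(inputs.get("genotypes", ""))
        pheno = Path(inputs.get("phenotypes", ""))
        for p, what in ((geno, "genotypes"), (pheno, "phenotypes")):
            if not p or not p.exists():
                errors.append(f"inputs.{what}: path {p} does not exist")
    else:
        errors.append("either a 'simulate' block or an 'inputs' block is required")
    if "out_dir" not in raw:
        errors.append("out_dir is required")
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))

    for key, default in _DEFAULTS_LOGGED:
        if key not in raw:
            log.info("config default applied: %s = %s", key, default)
    return RunConfig(
        out_dir=Path(raw["out_dir"]),
        traits=list(traits),
        models=list(models),
        alpha=float(alpha),
        k_folds=int(raw.get("k_folds", 10)),
        k_pcs=int(raw.get("k_pcs", 2)),
        maf_threshold=float(maf),
        imputation=raw.get("imputation", "marker_mean"),
        outlier_cutoff=float(raw.get("outlier_cutoff", 4.0)),
        boxcox=bool(raw.get("boxcox", True)),
        inner_folds=int(raw.get("inner_folds", 5)),
        seed=int(raw.get("seed", 0)),
        simulate=sim_cfg,
        genotype_path=geno,
        genotype_format=(raw.get("inputs") or {}).get("format", "tabular"),
        phenotype_path=pheno,
        use_transformed_blups=bool(raw.get("use_transformed_blups", True)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_blup_outputs(summaries: list[TraitSummary], out_dir: Path) -> None:
    """BlupTable CSV plus a JSON sidecar with variance components, H,
    SE, and the Box-Cox lambda per trait."""
    blup_table(summaries).to_csv(out_dir / "blups.csv", index_label="genotype_id")
    tr = blup_table(summaries, transformed=True)
    tr.to_csv(out_dir / "blups_transformed.csv", index_label="genotype_id")
    meta = {
        s.trait: {
            "variance_components": s.varcomp.components,
            "n_years": s.varcomp.n_years,
            "n_reps": s.varcomp.n_reps,
            "repeatability": s.repeatability,
            "repeatability_se": s.repeatability_se,
            "boxcox_lambda": s.boxcox_lambda,
            "boxcox_grid": [-2.0, 2.0, 0.01],
            "n_outliers_removed": s.n_outliers_removed,
        }
        for s in summaries
    }
    (out_dir / "blup_meta.json").write_text(json.dumps(meta, indent=2))


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure writes a FAILED marker naming the stage (and trait,
    when applicable) and re-raises; partial outputs are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info("run seed: %d", cfg.seed)
        log.info(
            "gap defaults in effect: GDD base 32F/ceiling 86F; clone-mean "
            "repeatability H = s2_g/(s2_g + s2_gy/y + s2_e/(y*r)); outlier "
            "cutoff |t| > %.3g; penalty by %d-fold inner CV over a 100-point "
            "log path", cfg.outlier_cutoff, cfg.inner_folds,
        )
        stage = "data"
        input_hashes = {}
        if cfg.simulate is not None:
            log.info("simulating panel: %s", cfg.simulate)
            matrix, pop_of, trial, truths = simulate_panel(cfg.simulate, cfg.traits)
            write_snp_matrix(matrix, out / "genotypes.tsv")
            trial.to_csv(out / "phenotypes.csv", index=False)
            truth_json = {
                t: {
                    "true_qtl_ids": tr.true_qtl_ids,
                    "true_effects": list(map(float, tr.true_effects)),
                    "realized_h2": tr.realized_h2,
                    "variance_components": tr.variance_components,
                }
                for t, tr in truths.items()
            }
            (out / "sim_truth.json").write_text(json.dumps(truth_json))
        else:
            matrix = read_snp_matrix(cfg.genotype_path, cfg.genotype_format)
            trial = pd.read_csv(cfg.phenotype_path)
            validate_trial_table(trial)
            pop_of = (
                trial.drop_duplicates("genotype_id")
                .set_index("genotype_id")["population_id"]
            )
            input_hashes = {
                "genotypes": _sha256(cfg.genotype_path),
                "phenotypes": _sha256(cfg.phenotype_path),
            }
        missing_traits = set(cfg.traits) - set(trial["trait"].unique())
        if missing_traits:
            raise ConfigError(f"traits absent from phenotype table: {sorted(missing_traits)}")

        stage = "prep-pheno"
        summaries: list[TraitSummary] = []
        for trait in cfg.traits:
            stage = f"prep-pheno:{trait}"
            s = prepare_trait(
                trial, trait, outlier_cutoff=cfg.outlier_cutoff, boxcox=cfg.boxcox
            )
            log.info(
                "trait %s: H=%.3f (SE %.3f), lambda=%s, outliers removed=%d",
                trait, s.repeatability, s.repeatability_se, s.boxcox_lambda,
                s.n_outliers_removed,
            )
            summaries.append(s)
        write_blup_outputs(summaries, out)

        stage = "prep-geno"
        imputed = impute_missing(matrix, cfg.imputation, rng_seed=cfg.seed)
        # structure PCs from the full imputed marker set (pre-MAF-filter)
        pcs = pca_scores(imputed, k=cfg.k_pcs)
        write_pc_scores(pcs, out / "pc_scores.csv")
        phenotyped = sorted(
            set.union(*(set(s.blups.index) for s in summaries))
        )
        sub = imputed.subset_samples(phenotyped)
        filtered = filter_maf(sub, cfg.maf_threshold)
        log.info(
            "markers: %d total, %d after MAF >= %g on %d phenotyped samples",
            matrix.n_markers, filtered.n_markers, cfg.maf_threshold, len(phenotyped),
        )

        stage = "cv"
        plan = make_group_folds(
            {g: pop_of[g] for g in phenotyped}, k=cfg.k_folds, rng_seed=cfg.seed
        )
        pd.Series(plan.assignment, name="fold").rename_axis("genotype_id").to_csv(
            out / "fold_plan.csv"
        )
        reports: list[CvReport] = []
        for s in summaries:
            stage = f"cv:{s.trait}"
            vals = (
                s.blups_transformed
                if cfg.use_transformed_blups and s.blups_transformed is not None
                else s.blups
            )
            resid = residualize_on_pcs(vals, pcs, cfg.k_pcs)
            geno_order = list(resid.index)
            x = filtered.subset_samples(geno_order)
            for model in cfg.models:
                rep = cross_validate(
                    x.dosages, x.samples, resid, plan, model,
                    trait=s.trait, repeatability=s.repeatability,
                    alpha=cfg.alpha, inner_folds=cfg.inner_folds,
                    rng_seed=cfg.seed,
                )
                log.info(
                    "trait %s model %s: mean r=%.3f, accuracy=%.3f",
                    s.trait, model, rep.mean_r, rep.accuracy,
                )
                reports.append(rep)

        stage = "report"
        table = report_table(reports)
        table.to_csv(out / "cv_report.csv", index=False)
        summary = (
            table.pivot(index="trait", columns="model", values="accuracy")
            .reindex(cfg.traits)
        )
        summary.insert(0, "mean", summary.mean(axis=1))
        summary.to_csv(out / "summary.csv")
        _plots(pcs, summary, out)

        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(cfg.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "input_sha256": input_hashes,
            "seed": cfg.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _plots(pcs, summary: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pcs.scores[:, 0], pcs.scores[:, 1], s=6, alpha=0.6)
    ax.set_xlabel(f"PC1 ({pcs.explained_variance[0]:.1%})")
    ax.set_ylabel(f"PC2 ({pcs.explained_variance[1]:.1%})")
    fig.tight_layout()
    fig.savefig(out / "pc_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    summary.drop(columns="mean").plot.bar(ax=ax)
    ax.set_ylabel("standardized accuracy")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(out / "accuracy_bars.png", dpi=120)
    plt.close(fig)
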