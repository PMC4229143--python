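"""Synthetic clonal-trial data with known truth.

Emulates the statistical structure of a clonally replicated association
panel: source populations nested in a few diverged ancestry clusters
(Balding-Nichols allele-frequency model), biallelic SNP dosages, an
additive polygenic trait, and plot-level records from a multi-year
randomized complete block design. Every downstream stage (imputation, PCA,
BLUPs, repeatability, genomic prediction, grouped CV) can be checked
against the simulated truth.

Markers are exchangeable given population frequencies: there is no
linkage map or LD decay, and dosages are diploidized regardless of the
nominal ploidy of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snp import SnpMatrix


@dataclass
class SimConfig:
    """Study-condition defaults mirror the panel being emulated:
    66 populations of 10 clones in 3 ancestry clusters, 2 replicates x
    3 years, ~12,000 SNPs with MAF >= 0.05, clone-mean repeatability
    around the upper range observed for morphological traits."""

    n_populations: int = 66
    clones_per_population: int = 10
    n_clusters: int = 3
    fst: float = 0.2
    n_markers: int = 12_000
    maf_floor: float = 0.05
    n_qtl: int = 200
    h2_clone_mean: float = 0.85
    n_years: int = 3
    n_reps: int = 2
    mu: float = 10.0
    sigma_year: float = 0.5  # SD of year effects
    sigma_block: float = 0.25  # SD of block(year) effects
    sigma_gxy: float = 0.5  # SD of genotype-by-year effects
    missing_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0 < self.h2_clone_mean < 1:
            raise ValueError("h2_clone_mean must lie in (0, 1)")
        for name in ("sigma_year", "sigma_block", "sigma_gxy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of one simulated trait."""

    true_qtl_ids: list[str]
    true_effects: np.ndarray
    true_genetic_values: pd.Series  # genotype_id -> g
    realized_h2: float
    cluster_labels: dict[str, int]  # population_id -> cluster
    variance_components: dict[str, float] = field(default_factory=dict)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_structure(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Population allele frequencies under a two-level Balding-Nichols model.

    Ancestral frequencies are uniform on [maf_floor, 1 - maf_floor];
    cluster frequencies are Beta-distributed around them with parameter
    ``fst``; population frequencies scatter around their cluster with the
    smaller within-cluster differentiation ``fst / 5``.

    Returns (pop_freqs with shape (n_populations, n_markers),
    cluster_label per population).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(1)[0])
    m = cfg.n_markers
    anc = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=m)

    def balding_nichols(p: np.ndarray, f: float, size: tuple) -> np.ndarray:
        shape = (1.0 - f) / f
        a = np.clip(p * shape, 1e-6, None)
        b = np.clip((1.0 - p) * shape, 1e-6, None)
        return np.clip(rng.beta(a, b, size=size), 1e-4, 1 - 1e-4)

    cluster_freqs = balding_nichols(anc, cfg.fst, (cfg.n_clusters, m))
    labels = np.arange(cfg.n_populations) % cfg.n_clusters
    pop_freqs = balding_nichols(
        cluster_freqs[labels], cfg.fst / 5.0, (cfg.n_populations, m)
    )
    return pop_freqs, labels


def simulate_genotypes(
    pop_freqs: np.ndarray, cfg: SimConfig
) -> tuple[SnpMatrix, pd.Series]:
    """Binomial(2, p) dosages per clone; returns the matrix and the
    genotype -> population map. Clones of one population are distinct
    genotypes drawn from the same population frequencies."""
    if np.any((pop_freqs <= 0) | (pop_freqs >= 1)):
        raise ValueError("population frequencies must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(2)[1])
    n_pop, m = pop_freqs.shape
    samples: list[str] = []
    pops: list[str] = []
    rows = []
    for p_idx in range(n_pop):
        pop_id = f"POP{p_idx + 1:03d}"
        dose = rng.binomial(2, pop_freqs[p_idx], size=(cfg.clones_per_population, m))
        rows.append(dose)
        for c_idx in range(cfg.clones_per_population):
            samples.append(f"{pop_id}_C{c_idx + 1:02d}")
            pops.append(pop_id)
    dosages = np.vstack(rows).astype(float)
    mask = np.zeros_like(dosages, dtype=bool)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        # never blank out an entire marker
        empty = mask.all(axis=0)
        mask[0, empty] = False
    markers = [f"S{j + 1:05d}" for j in range(m)]
    matrix = SnpMatrix(
        samples=samples, markers=markers, dosages=np.where(mask, 0.0, dosages),
        missing_mask=mask,
    )
    return matrix, pd.Series(pops, index=samples, name="population_id")


def required_residual_variance(cfg: SimConfig, s2_g: float = 1.0) -> float:
    """Residual variance that realizes the target clone-mean repeatability
    given s2_g and sigma_gxy; raises if the target is infeasible."""
    y, r = cfg.n_years, cfg.n_reps
    s2_gy = cfg.sigma_gxy**2
    h_max = s2_g / (s2_g + s2_gy / y)
    if cfg.h2_clone_mean >= h_max:
        raise ValueError(
            f"h2_clone_mean={cfg.h2_clone_mean} unattainable with "
            f"sigma_gxy={cfg.sigma_gxy}: feasible bound is H < {h_max:.4f}"
        )
    s2_e = y * r * (s2_g / cfg.h2_clone_mean - s2_g - s2_gy / y)
    return float(s2_e)


def simulate_phenotypes(
    m: SnpMatrix,
    cfg: SimConfig,
    pop_of: pd.Series,
    cluster_labels: np.ndarray | None = None,
    trait: str = "trait",
    seed_offset: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive polygenic trait over a multi-year RCBD.

    QTL effects are drawn N(0, 1) on centered dosages and rescaled so the
    genetic variance among genotypes is 1; year, block(year), genotype-by-
    year, and residual effects are added with the configured SDs, the
    residual SD solved so the clone-mean repeatability equals the target.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.rng_seed).spawn(4 + seed_offset)[3 + seed_offset]
    )
    n = m.n_samples
    if cfg.n_qtl > 0:
        qtl_idx = np.sort(rng.choice(m.n_markers, size=cfg.n_qtl, replace=False))
        effects = rng.normal(0.0, 1.0, size=cfg.n_qtl)
        dq = m.dosages[:, qtl_idx]
        gv = (dq - dq.mean(axis=0)) @ effects
        sd = gv.std(ddof=0)
        if sd > 0:
            effects /= sd
            gv /= sd
        s2_g = float(np.var(gv, ddof=0))
        qtl_ids = [m.markers[j] for j in qtl_idx]
    else:
        qtl_ids, effects = [], np.array([])
        gv = np.zeros(n)
        s2_g = 0.0

    s2_e = required_residual_variance(cfg, s2_g=1.0)
    s2_gy = cfg.sigma_gxy**2
    y_n, r_n = cfg.n_years, cfg.n_reps
    years = [2009 + i for i in range(y_n)]
    year_eff = rng.normal(0.0, cfg.sigma_year, size=y_n)
    block_eff = rng.normal(0.0, cfg.sigma_block, size=(y_n, r_n))
    gxy = rng.normal(0.0, cfg.sigma_gxy, size=(n, y_n))

    records = []
    for yi, yr in enumerate(years):
        eps = rng.normal(0.0, np.sqrt(s2_e), size=(n, r_n))
        for ri in range(r_n):
            vals = (
                cfg.mu + year_eff[yi] + block_eff[yi, ri]
                + gv + gxy[:, yi] + eps[:, ri]
            )
            for si, s in enumerate(m.samples):
                records.append(
                    (s, pop_of[s], yr, "F1", f"B{ri + 1}", trait, vals[si])
                )
    table = pd.DataFrame(records, columns=[
        "genotype_id", "population_id", "year", "field_id", "block_id",
        "trait", "value",
    ])
    realized_h2 = (
        s2_g / (s2_g + s2_gy / y_n + s2_e / (y_n * r_n)) if s2_g > 0 else 0.0
    )
    clusters = {}
    if cluster_labels is not None:
        pop_ids = sorted(set(pop_of))
        clusters = {p: int(cluster_labels[i]) for i, p in enumerate(pop_ids)}
    truth = SimTruth(
        true_qtl_ids=qtl_ids,
        true_effects=effects,
        true_genetic_values=pd.Series(gv, index=m.samples),
        realized_h2=float(realized_h2),
        cluster_labels=clusters,
        variance_components={
            "genotype": s2_g, "genotype_x_year": s2_gy, "residual": s2_e,
            "year": cfg.sigma_year**2, "block_in_year": cfg.sigma_block**2,
        },
    )
    return table, truth


def simulate_panel(
    cfg: SimConfig, traits: list[str] | None = None
) -> tuple[SnpMatrix, pd.Series, pd.DataFrame, dict[str, SimTruth]]:
    """Full panel: genotypes + one trial table covering the given traits."""
    traits = traits or ["trait"]
    pop_freqs, labels = simulate_structure(cfg)
    matrix, pop_of = simulate_genotypes(pop_freqs, cfg)
    tables = []
    truths: dict[str, SimTruth] = {}
    for i, tr in enumerate(traits):
        tab, truth = simulate_phenotypes(
            matrix, cfg, pop_of, cluster_labels=labels, trait=tr, seed_offset=i
        )
        tables.append(tab)
        truths[tr] = truth
    return matrix, pop_of, pd.concat(tables, ignore_index=True), truths


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Ratio-of-means Hudson-style Fst from two frequency vectors
    (population-level frequencies, no sampling correction)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)
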