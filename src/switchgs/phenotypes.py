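"""Phenotype preparation for clonally replicated multi-year trials.

Plot-level observations (genotype x year x block) are screened for
outliers with studentized deleted residuals, reduced to one value per
genotype by mixed-model BLUPs, summarized by clone-mean repeatability
(with a delta-method standard error), and optionally Box-Cox transformed
before genomic prediction.

The trial table is a long-format DataFrame with columns
``genotype_id, population_id, year, field_id, block_id, trait, value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RemlResult, reml_fit

TRIAL_COLUMNS = [
    "genotype_id", "population_id", "year", "field_id", "block_id",
    "trait", "value",
]


def validate_trial_table(t: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format trial table invariants."""
    missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    pops = t.groupby("genotype_id")["population_id"].nunique()
    if (pops > 1).any():
        bad = pops[pops > 1].index.tolist()[:5]
        raise ValueError(f"genotypes mapped to multiple populations: {bad}")
    dup = t.dropna(subset=["value"]).duplicated(
        subset=["genotype_id", "year", "block_id", "trait"]
    )
    if dup.any():
        raise ValueError("duplicate (genotype, year, block, trait) records")
    return t


@dataclass
class VarComp:
    """Estimated variance components of the trial model.

    ``components`` holds the named variances (genotype, genotype_x_year,
    year, block_in_year, optionally field, and residual); the asymptotic
    covariance comes from the inverse average-information matrix of the
    REML fit. ``n_years``/``n_reps`` are the design constants entering
    the clone-mean repeatability.
    """

    components: dict[str, float]
    asymptotic_covariance: pd.DataFrame
    n_years: int
    n_reps: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValueError("variance components must be non-negative")


@dataclass
class TraitSummary:
    trait: str
    varcomp: VarComp
    repeatability: float
    repeatability_se: float
    boxcox_lambda: float | None
    blups: pd.Series  # genotype_id -> BLUP (trait scale: intercept + effect)
    blups_transformed: pd.Series | None = None
    n_outliers_removed: int = 0
    reml: RemlResult | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Outlier screening


def flag_outliers(
    t: pd.DataFrame, trait: str, cutoff: float = 4.0
) -> pd.Index:
    """Indices of records whose studentized deleted residual exceeds cutoff.

    The screening model treats year, field, block(year), and population as
    random effects. The deleted (externally studentized) residual for
    record i is r_i * sqrt((nu - 1) / (nu - r_i^2)) where r_i is the
    internally studentized conditional residual and nu the effective
    residual degrees of freedom.
    """
    sub = t[(t["trait"] == trait) & t["value"].notna()]
    if len(sub) < 10:
        raise ValueError(f"trait {trait!r}: need >= 10 non-missing records")
    y = sub["value"].to_numpy(dtype=float)
    terms = {
        "year": sub["year"].to_numpy(),
        "block_in_year": (
            sub["year"].astype(str) + "/" + sub["block_id"].astype(str)
        ).to_numpy(),
        "population": sub["population_id"].to_numpy(),
    }
    if sub["field_id"].nunique() > 1:
        terms["field"] = sub["field_id"].to_numpy()
    try:
        res = reml_fit(y, terms, compute_leverage=True)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"outlier model failed for trait {trait!r}: {exc}")
    e = res.residuals
    h = np.clip(res.leverage, 0.0, 1.0 - 1e-10)
    s2e = res.components["residual"]
    nu = max(len(y) - float(np.sum(h)), 3.0)
    r = e / np.sqrt(s2e * (1.0 - h))
    r2 = np.minimum(r**2, nu - 1e-6)
    t_del = r * np.sqrt((nu - 1.0) / (nu - r2))
    return sub.index[np.abs(t_del) > cutoff]


def remove_outliers(
    t: pd.DataFrame, trait: str, cutoff: float = 4.0
) -> tuple[pd.DataFrame, int]:
    flagged = flag_outliers(t, trait, cutoff)
    return t.drop(index=flagged), len(flagged)


# ---------------------------------------------------------------------------
# BLUP model


def fit_blup_model(
    t: pd.DataFrame,
    trait: str,
    include_population: bool = False,
) -> tuple[VarComp, pd.Series, RemlResult]:
    """REML fit of the trial variance-components model for one trait.

    Model: value = mu + year + block(year) [+ field] + genotype
    + genotype x year + residual, all non-intercept terms random.
    Population is deliberately not a term by default: population-level
    structure is removed downstream by regression on SNP principal
    components, and fitting it twice would doubly correct structure.

    Returns the variance components, the per-genotype BLUPs on the trait
    scale (intercept + predicted genotype effect), and the raw REML result.
    """
    sub = t[(t["trait"] == trait) & t["value"].notna()]
    years = sub["year"].nunique()
    blocks = sub["block_id"].nunique()
    if years < 2 and blocks < 2:
        raise ValueError(
            f"trait {trait!r}: need >= 2 years or >= 2 blocks to separate "
            "variance components"
        )
    y = sub["value"].to_numpy(dtype=float)
    terms: dict[str, np.ndarray] = {
        "genotype": sub["genotype_id"].to_numpy(),
        "genotype_x_year": (
            sub["genotype_id"].astype(str) + "@" + sub["year"].astype(str)
        ).to_numpy(),
        "year": sub["year"].to_numpy(),
        "block_in_year": (
            sub["year"].astype(str) + "/" + sub["block_id"].astype(str)
        ).to_numpy(),
    }
    if sub["field_id"].nunique() > 1:
        terms["field"] = sub["field_id"].to_numpy()
    if include_population:
        terms["population"] = sub["population_id"].to_numpy()
    res = reml_fit(y, terms)
    if not res.converged:
        raise RuntimeError(f"REML did not converge for trait {trait!r}")
    # replicates per genotype-year cell (mode over the observed cells)
    reps = (
        sub.groupby(["genotype_id", "year"])["block_id"].nunique().mode().iloc[0]
    )
    vc = VarComp(
        components=res.components,
        asymptotic_covariance=res.cov,
        n_years=int(years),
        n_reps=int(reps),
    )
    blups = res.u["genotype"] + float(res.beta[0])
    blups.index.name = "genotype_id"
    return vc, blups, res


# ---------------------------------------------------------------------------
# Repeatability


def clone_mean_repeatability(v: VarComp) -> float:
    """H = s2_g / (s2_g + s2_gy / y + s2_e / (y * r)).

    The clone-mean repeatability: the share of the variance of a
    genotype's mean (over y years and r replicates) that is genetic. It
    upper-bounds broad-sense heritability.
    """
    s2g = v.components.get("genotype", 0.0)
    s2gy = v.components.get("genotype_x_year", 0.0)
    s2e = v.components["residual"]
    yy, r = v.n_years, v.n_reps
    if yy < 1 or r < 1:
        raise ValueError("n_years and n_reps must be >= 1")
    denom = s2g + s2gy / yy + s2e / (yy * r)
    if denom == 0:
        raise ValueError("repeatability undefined: all variance components zero")
    return s2g / denom


def repeatability_se(v: VarComp) -> float:
    """Delta-method standard error of the clone-mean repeatability.

    SE = sqrt(g' C g) with g the gradient of H in (s2_g, s2_gy, s2_e)
    and C their asymptotic covariance from the REML information matrix.
    """
    s2g = v.components.get("genotype", 0.0)
    s2gy = v.components.get("genotype_x_year", 0.0)
    s2e = v.components["residual"]
    yy, r = v.n_years, v.n_reps
    denom = s2g + s2gy / yy + s2e / (yy * r)
    if denom == 0:
        raise ValueError("repeatability undefined: zero denominator")
    # dH/ds2_g = (denom - s2g)/denom^2 ; dH/ds2_gy = -s2g/(y denom^2) ; etc.
    grad = {
        "genotype": (denom - s2g) / denom**2,
        "genotype_x_year": -s2g / (yy * denom**2),
        "residual": -s2g / (yy * r * denom**2),
    }
    names = [k for k in grad if k in v.asymptotic_covariance.index]
    c = v.asymptotic_covariance.loc[names, names].to_numpy()
    eig = np.linalg.eigvalsh((c + c.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValueError("asymptotic covariance is not positive semi-definite")
    gvec = np.array([grad[k] for k in names])
    return float(np.sqrt(max(gvec @ c @ gvec, 0.0)))


# ---------------------------------------------------------------------------
# Box-Cox


def boxcox_optimal(
    values: np.ndarray,
    grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
    shift: bool = False,
) -> tuple[float, np.ndarray]:
    """Box-Cox transform with lambda chosen on a grid by profile likelihood.

    values must be strictly positive; with ``shift`` enabled, non-positive
    inputs are first shifted by (1 - min). Returns (lambda, transformed).
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("constant vector: Box-Cox lambda undefined")
    if values.min() <= 0:
        if not shift:
            raise ValueError(
                "non-positive values; enable shift=True to offset by (1 - min)"
            )
        values = values + (1.0 - values.min())
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    lls = np.array([stats.boxcox_llf(lam, values) for lam in lams])
    lam = float(lams[np.argmax(lls)])
    transformed = stats.boxcox(values, lmbda=lam)
    return lam, transformed


# ---------------------------------------------------------------------------
# Per-trait driver


def prepare_trait(
    t: pd.DataFrame,
    trait: str,
    outlier_cutoff: float = 4.0,
    boxcox: bool = True,
    include_population: bool = False,
) -> TraitSummary:
    """Outlier screen -> BLUP model -> repeatability -> Box-Cox, one trait."""
    validate_trial_table(t)
    clean, n_removed = remove_outliers(t, trait, outlier_cutoff)
    vc, blups, res = fit_blup_model(clean, trait, include_population)
    h = clone_mean_repeatability(vc)
    se = repeatability_se(vc)
    lam = None
    transformed = None
    if boxcox:
        lam, tvals = boxcox_optimal(blups.to_numpy(), shift=True)
        transformed = pd.Series(tvals, index=blups.index)
    return TraitSummary(
        trait=trait,
        varcomp=vc,
        repeatability=h,
        repeatability_se=se,
        boxcox_lambda=lam,
        blups=blups,
        blups_transformed=transformed,
        n_outliers_removed=n_removed,
        reml=res,
    )


def blup_table(summaries: list[TraitSummary], transformed: bool = False) -> pd.DataFrame:
    """Wide per-genotype table of BLUPs across traits."""
    cols = {}
    for s in summaries:
        vals = s.blups_transformed if (transformed and s.blups_transformed is not None) else s.blups
        cols[s.trait] = vals
    return pd.DataFrame(cols)
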