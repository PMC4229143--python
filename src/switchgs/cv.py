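"""Population-aware cross-validation and standardized prediction accuracy.

Clones are nested within source populations, so random k-fold splits leak
family information and inflate accuracy. Folds are therefore built over
whole populations: a population is never split between training and
prediction sets. Accuracy is reported on the genetic scale by dividing the
mean fold Pearson correlation by the square root of the trait's clone-mean
repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import GsFit, fit_penalized, fit_rrblup, predict, select_lambda
from .snp import PcScores


@dataclass
class FoldPlan:
    """Assignment of genotypes to k folds, whole populations together."""

    k: int
    assignment: dict[str, int]  # genotype_id -> fold in 1..k
    grouping: dict[str, str]  # genotype_id -> population_id
    rng_seed: int

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(1, self.k + 1)):
            raise ValueError("fold indices must lie in 1..k")
        by_pop: dict[str, set[int]] = {}
        for g, f in self.assignment.items():
            by_pop.setdefault(self.grouping[g], set()).add(f)
        split = [p for p, fs in by_pop.items() if len(fs) > 1]
        if split:
            raise ValueError(f"populations split across folds: {split[:5]}")

    def fold_members(self, fold: int) -> list[str]:
        return [g for g, f in self.assignment.items() if f == fold]


@dataclass
class CvReport:
    """Per-fold correlations and standardized accuracy for one trait/model."""

    trait: str
    model: str
    fold_correlations: np.ndarray
    repeatability: float

    @property
    def k(self) -> int:
        return len(self.fold_correlations)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.fold_correlations))

    @property
    def spread(self) -> float:
        """Standard deviation of the fold correlations."""
        return float(np.std(self.fold_correlations, ddof=1))

    @property
    def spread_se(self) -> float:
        """Standard-error convention: spread / sqrt(k)."""
        return self.spread / np.sqrt(self.k)

    @property
    def accuracy(self) -> float:
        return standardized_accuracy(self.mean_r, self.repeatability)


def standardized_accuracy(mean_r: float, h: float) -> float:
    """mean fold correlation / sqrt(repeatability); never clipped."""
    if not 0.0 < h <= 1.0:
        raise ValueError(f"repeatability must lie in (0, 1], got {h}")
    return mean_r / np.sqrt(h)


def residualize_on_pcs(
    values: pd.Series, pcs: PcScores, k_pcs: int = 2
) -> pd.Series:
    """Residuals of an OLS regression of the trait on the first k PCs.

    Removes population-structure signal (ecotype/ploidy clusters) from the
    response before genomic prediction.
    """
    if k_pcs < 1 or k_pcs > pcs.k:
        raise ValueError(f"k_pcs must lie in [1, {pcs.k}]")
    idx = {s: i for i, s in enumerate(pcs.samples)}
    missing = [s for s in values.index if s not in idx]
    if missing:
        raise ValueError(f"samples without PC scores: {missing[:5]}")
    rows = [idx[s] for s in values.index]
    design = np.column_stack(
        [np.ones(len(values)), pcs.scores[rows, :k_pcs]]
    )
    y = values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return pd.Series(y - design @ coef, index=values.index)


def make_group_folds(
    grouping: dict[str, str], k: int = 10, rng_seed: int = 0
) -> FoldPlan:
    """Greedy balanced assignment of whole populations to k folds.

    Populations are shuffled with the seed, then each is placed in the
    currently smallest fold (by genotype count); deterministic given seed.
    """
    pops: dict[str, list[str]] = {}
    for g, p in grouping.items():
        pops.setdefault(p, []).append(g)
    if len(pops) < k:
        raise ValueError(f"{len(pops)} populations < {k} folds")
    rng = np.random.default_rng(rng_seed)
    order = sorted(pops)
    rng.shuffle(order)
    sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for p in order:
        f = int(np.argmin(sizes))
        sizes[f] += len(pops[p])
        for g in pops[p]:
            assignment[g] = f + 1
    return FoldPlan(k=k, assignment=assignment, grouping=dict(grouping), rng_seed=rng_seed)


def _fit_model(x, y, model: str, alpha: float, inner_folds: int, seed: int,
               marker_ids, n_lambda: int) -> GsFit:
    if model == "rrblup":
        return fit_rrblup(x, y, marker_ids=marker_ids)
    a = 1.0 if model == "lasso" else alpha
    lam = select_lambda(x, y, a, n_inner_folds=inner_folds, rng_seed=seed,
                        n_lambda=n_lambda)
    return fit_penalized(x, y, a, lam, marker_ids=marker_ids)


def cross_validate(
    dosages: np.ndarray,
    samples: list[str],
    y: pd.Series,
    plan: FoldPlan,
    model: str,
    trait: str = "",
    repeatability: float = 1.0,
    alpha: float = 0.5,
    inner_folds: int = 5,
    rng_seed: int = 0,
    marker_ids: list[str] | None = None,
    n_lambda: int = 100,
) -> CvReport:
    """Population-grouped k-fold CV of one prediction model on one trait.

    ``dosages`` rows follow ``samples``; ``y`` is the (residualized)
    response indexed by genotype_id. Penalty selection for the penalized
    models is nested inside the training folds and never sees held-out
    phenotypes.
    """
    dosages = np.asarray(dosages, dtype=float)
    sample_pos = {s: i for i, s in enumerate(samples)}
    genos = [g for g in y.index if g in plan.assignment]
    if len(genos) < len(y):
        raise ValueError("phenotyped genotypes missing from the fold plan")
    rs = []
    for fold in range(1, plan.k + 1):
        test_g = [g for g in genos if plan.assignment[g] == fold]
        train_g = [g for g in genos if plan.assignment[g] != fold]
        if len(test_g) < 3:
            raise ValueError(f"fold {fold} has fewer than 3 genotypes")
        # leakage guard: train and prediction populations must be disjoint
        overlap = {plan.grouping[g] for g in train_g} & {
            plan.grouping[g] for g in test_g
        }
        assert not overlap, f"population leakage across folds: {overlap}"
        xtr = dosages[[sample_pos[g] for g in train_g]]
        xte = dosages[[sample_pos[g] for g in test_g]]
        ytr = y.loc[train_g].to_numpy(dtype=float)
        yte = y.loc[test_g].to_numpy(dtype=float)
        fit = _fit_model(xtr, ytr, model, alpha, inner_folds,
                         rng_seed + fold, marker_ids, n_lambda)
        pred = predict(fit, xte)
        if np.ptp(pred) == 0 or np.ptp(yte) == 0:
            warnings.warn(
                f"constant predictions in fold {fold}; recording r = 0",
                RuntimeWarning,
            )
            rs.append(0.0)
        else:
            rs.append(float(stats.pearsonr(yte, pred)[0]))
    return CvReport(
        trait=trait,
        model=model,
        fold_correlations=np.asarray(rs),
        repeatability=repeatability,
    )


def repeatability_accuracy_spearman(
    h_by_trait: dict[str, float], raw_r_by_trait: dict[str, float]
) -> float:
    """Spearman rank correlation of repeatability vs unstandardized mean r.

    Ties receive average ranks (scipy convention)."""
    traits = sorted(h_by_trait)
    if sorted(raw_r_by_trait) != traits:
        raise ValueError("trait sets differ between the two maps")
    if len(traits) < 3:
        raise ValueError("need at least 3 traits")
    h = [h_by_trait[t] for t in traits]
    r = [raw_r_by_trait[t] for t in traits]
    return float(stats.spearmanr(h, r)[0])


def report_table(reports: list[CvReport]) -> pd.DataFrame:
    """CSV-ready table: trait, model, fold_1..fold_k, mean_r, spread,
    repeatability, accuracy."""
    rows = []
    for rep in reports:
        row = {"trait": rep.trait, "model": rep.model}
        row.update({f"fold_{i+1}": r for i, r in enumerate(rep.fold_correlations)})
        row.update(
            mean_r=rep.mean_r, spread=rep.spread,
            repeatability=rep.repeatability, accuracy=rep.accuracy,
        )
        rows.append(row)
    return pd.DataFrame(rows)
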