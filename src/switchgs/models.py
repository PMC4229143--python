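"""Whole-genome prediction models: RR-BLUP, LASSO, and elastic net.

RR-BLUP treats every marker effect as random with a common variance and
sets the ridge parameter from the REML ratio of residual to marker
variance, solved in the n x n kernel space (efficient when the marker
count far exceeds the sample count). LASSO and elastic net minimize

    (1/2n) ||y - mu - Z b||^2 + lambda * [alpha ||b||_1 + (1-alpha)/2 ||b||^2]

by cyclic coordinate descent (scikit-learn's solver), on internally
standardized markers with effects returned on the original dosage scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import helmert as scipy_helmert
from scipy.optimize import minimize_scalar
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

MODELS = ("rrblup", "lasso", "elastic_net")


@dataclass
class GsFit:
    """A fitted whole-genome prediction model."""

    model: str
    intercept: float
    effects: np.ndarray  # per-marker, original dosage scale
    marker_ids: list[str]
    penalty: float = 0.0  # lambda (penalized) or delta = s2_e/s2_u (rrblup)
    mixing: float | None = None  # alpha, elastic net / lasso
    variance_estimates: dict[str, float] | None = None  # rrblup only

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.effects) != len(self.marker_ids):
            raise ValueError("effects length must match marker_ids")
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


def predict(fit: GsFit, x_new: np.ndarray, marker_ids: list[str] | None = None) -> np.ndarray:
    """Predicted values: intercept + dosages . effects."""
    x_new = np.asarray(x_new, dtype=float)
    if marker_ids is not None and list(marker_ids) != list(fit.marker_ids):
        bad = [m for m in marker_ids if m not in set(fit.marker_ids)][:5]
        raise ValueError(
            f"marker ids do not match the fitted model (e.g. {bad or 'order differs'})"
        )
    if x_new.shape[1] != len(fit.effects):
        raise ValueError(
            f"x_new has {x_new.shape[1]} markers, model has {len(fit.effects)}"
        )
    return fit.intercept + x_new @ fit.effects


# ---------------------------------------------------------------------------
# RR-BLUP


def fit_rrblup(
    x: np.ndarray,
    y: np.ndarray,
    marker_ids: list[str] | None = None,
) -> GsFit:
    """Ridge-regression BLUP with the ridge parameter set by REML.

    The restricted likelihood of delta = s2_e/s2_u is profiled on the
    spectrum of the projected marker kernel Z Z' and optimized in one
    dimension; marker effects are the BLUPs
    u = Z' (Z Z' + delta I)^-1 (y - mu).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(p)]

    k = x @ x.T
    ones = np.ones(n)
    # restricted likelihood on error contrasts: rotate into an orthonormal
    # basis of the intercept's complement (exact for any kernel rank)
    a = scipy_helmert(n)  # (n-1) x n, rows orthonormal, orthogonal to 1
    t = a @ k @ a.T
    xi_r, vec = np.linalg.eigh((t + t.T) / 2.0)
    if xi_r.min() < -1e-8 * max(1.0, xi_r.max()):
        warnings.warn("kernel numerically indefinite; flooring eigenvalues at 0",
                      RuntimeWarning)
    xi_r = np.maximum(xi_r, 0.0)
    eta = vec.T @ (a @ y)
    df = n - 1

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi_r + d
        s2u = float(np.sum(eta**2 / denom)) / df
        if s2u <= 0:
            return np.inf
        return 0.5 * (df * np.log(s2u) + float(np.sum(np.log(denom))))

    res = minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    s2u = float(np.sum(eta**2 / (xi_r + delta))) / df
    s2e = delta * s2u

    h = k + delta * np.eye(n)
    hinv_y = np.linalg.solve(h, y)
    hinv_1 = np.linalg.solve(h, ones)
    mu = float(ones @ hinv_y) / float(ones @ hinv_1)
    alpha_vec = np.linalg.solve(h, y - mu * ones)
    effects = x.T @ alpha_vec
    return GsFit(
        model="rrblup",
        intercept=mu,
        effects=effects,
        marker_ids=list(marker_ids),
        penalty=delta,
        variance_estimates={"marker": s2u, "residual": s2e},
    )


# ---------------------------------------------------------------------------
# Penalized regression (LASSO / elastic net)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance marker(s): effects set to 0",
            RuntimeWarning,
        )
    sd_safe = np.where(zero, 1.0, sd)
    return (x - mean) / sd_safe, mean, sd_safe


def fit_penalized(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    marker_ids: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> GsFit:
    """Elastic net (alpha=1: LASSO; alpha=0: ridge) at a fixed penalty."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = x.shape
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(p)]
    z, mean, sd = _standardize(x)
    ybar = float(y.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            tol=tol, max_iter=max_iter,
        ).fit(z, y - ybar)
    if est.n_iter_ is not None and est.n_iter_ >= max_iter:
        raise RuntimeError(
            f"coordinate descent did not converge (lambda={lam}, alpha={alpha})"
        )
    b_std = est.coef_
    effects = b_std / sd
    intercept = ybar - float(mean @ effects)
    model = "lasso" if alpha == 1.0 else "elastic_net"
    return GsFit(
        model=model,
        intercept=intercept,
        effects=effects,
        marker_ids=list(marker_ids),
        penalty=float(lam),
        mixing=float(alpha),
    )


def lambda_path(
    x_std: np.ndarray, y: np.ndarray, alpha: float,
    n_lambda: int = 100, ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down to lambda_max * ratio."""
    n = len(y)
    yc = y - y.mean()
    alpha_eff = max(alpha, 1e-3)  # ridge has no finite lambda_max
    lam_max = float(np.max(np.abs(x_std.T @ yc)) / (n * alpha_eff))
    if lam_max == 0:
        raise ValueError("degenerate path: lambda_max is 0 (constant response?)")
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_inner_folds: int = 5,
    rng_seed: int = 0,
    n_lambda: int = 100,
) -> float:
    """Pick the penalty minimizing inner-CV mean squared error.

    Inner folds are population-agnostic random splits of the training
    set; the path is shared across folds so MSE curves are comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_inner_folds < 2:
        raise ValueError("need at least 2 inner folds")
    n = len(y)
    z, _, _ = _standardize(x)
    path = lambda_path(z, y, alpha, n_lambda=n_lambda)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_inner_folds)
    sq_err = np.zeros((n_inner_folds, len(path)))
    alpha_eff = max(alpha, 1e-3)
    for i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, val_idx)
        zt, yt = z[train_idx], y[train_idx]
        zm = zt.mean(axis=0)
        ym = yt.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            _, coefs, _ = enet_path(
                zt - zm, yt - ym, l1_ratio=alpha_eff, alphas=path,
            )
        # enet_path returns coefs for alphas sorted descending = our path order
        pred = (z[val_idx] - zm) @ coefs + ym
        sq_err[i] = ((pred - y[val_idx][:, None]) ** 2).mean(axis=0)
    mse = sq_err.mean(axis=0)
    return float(path[int(np.argmin(mse))])
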