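"""Restricted maximum likelihood for independent variance components.

Fits y = X beta + sum_i Z_i u_i + e with u_i ~ N(0, s2_i I) and
e ~ N(0, s2_e I), where each Z_i is an indicator (grouping) matrix.
Estimation runs on Henderson's mixed-model equations: the coefficient
matrix

    C = [[X'X, X'Z], [Z'X, Z'Z + s2_e D^-1]]

is factorized once per iteration, giving the REML log-likelihood, the
EM update, and (via the average-information matrix) a quasi-Newton
update and the asymptotic covariance of the estimates. EM steps are used
for warm-up and as a fallback whenever an AI step leaves the parameter
space or decreases the restricted likelihood; variance components are
kept non-negative by a small positive floor.

This covers the crossed random-effects layouts of clonal field trials
(year, block-in-year, genotype, genotype-by-year) without requiring any
balance in the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse


class RemlError(RuntimeError):
    """REML iteration failed to converge."""


@dataclass
class RemlResult:
    """Variance components and random-effect predictions from one fit."""

    components: dict[str, float]  # includes "residual"
    cov: pd.DataFrame  # asymptotic covariance (AI inverse), component order
    beta: np.ndarray  # fixed effects (intercept first)
    u: dict[str, pd.Series]  # BLUPs per component, indexed by level
    loglik: float  # restricted log-likelihood (up to constant)
    n_iter: int
    converged: bool
    boundary: list[str]  # components estimated at (near) zero
    leverage: np.ndarray | None = None  # diag of the mixed-model hat matrix
    residuals: np.ndarray | None = None  # conditional residuals y - Xb - Zu

    @property
    def cov_matrix(self) -> np.ndarray:
        return self.cov.to_numpy()


def _indicator(labels: np.ndarray) -> tuple[sparse.csr_matrix, list]:
    levels, codes = np.unique(labels, return_inverse=True)
    n = len(labels)
    z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return z, list(levels)


def reml_fit(
    y: np.ndarray,
    terms: dict[str, np.ndarray],
    x: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    n_em_warmup: int = 3,
    compute_leverage: bool = False,
) -> RemlResult:
    """Fit the variance-components model by AI-REML with EM safeguards.

    Parameters
    ----------
    y : response vector.
    terms : mapping term name -> label vector (length n); one independent
        variance component per term.
    x : fixed-effects design; default an intercept column.
    compute_leverage : also return the diagonal of the hat matrix and the
        conditional residuals (used by the outlier screen).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if x is None:
        x = np.ones((n, 1))
    p = x.shape[1]
    names = list(terms)
    zs, level_names = zip(*(_indicator(np.asarray(terms[k])) for k in names))
    q_sizes = [z.shape[1] for z in zs]
    z_all = sparse.hstack(zs, format="csr")
    q = z_all.shape[1]
    offsets = np.concatenate([[0], np.cumsum(q_sizes)])

    # fixed cross-products
    xtx = x.T @ x
    xtz = x.T @ z_all  # p x q (dense result)
    xtz = np.asarray(xtz.todense()) if sparse.issparse(xtz) else np.asarray(xtz)
    g = np.asarray((z_all.T @ z_all).todense())
    xty = x.T @ y
    zty = z_all.T @ y

    vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if vary == 0:
        raise RemlError("response has zero variance")
    floor = 1e-8 * vary
    c = len(names)
    theta = np.full(c + 1, vary / (c + 1))  # components..., residual last

    def assemble(theta_):
        s2e = theta_[-1]
        dinv = np.concatenate(
            [np.full(q_sizes[i], s2e / theta_[i]) for i in range(c)]
        )
        cm = np.zeros((p + q, p + q))
        cm[:p, :p] = xtx
        cm[:p, p:] = xtz
        cm[p:, :p] = xtz.T
        cm[p:, p:] = g
        cm[p + np.arange(q), p + np.arange(q)] += dinv
        return cm

    def factor_and_loglik(theta_):
        """Return (chol, sol, e, loglik); sol = [beta, u]."""
        s2e = theta_[-1]
        cm = assemble(theta_)
        try:
            cf = linalg.cho_factor(cm, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise RemlError(f"singular mixed-model equations: {exc}") from exc
        rhs = np.concatenate([xty, zty])
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        e = y - x @ sol[:p] - z_all @ sol[p:]
        ypy = float(y @ e) / s2e  # y'Py
        logdet_c = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdet = (
            (n - p - q) * np.log(s2e)
            + logdet_c
            + sum(q_sizes[i] * np.log(theta_[i]) for i in range(c))
        )
        ll = -0.5 * (logdet + ypy)
        return cf, sol, e, ll

    def p_apply(cf, f, s2e):
        """Apply the REML projection P to a vector using the factored MME."""
        rhs = np.concatenate([x.T @ f, z_all.T @ f])
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        return (f - x @ sol[:p] - z_all @ sol[p:]) / s2e

    def gradient_and_traces(cf, sol, e, theta_):
        s2e = theta_[-1]
        cinv = linalg.cho_solve(cf, np.eye(p + q), check_finite=False)
        diag_cinv_u = np.diag(cinv)[p:]
        tr_blocks = np.array(
            [diag_cinv_u[offsets[i]: offsets[i + 1]].sum() for i in range(c)]
        )
        py = e / s2e
        u = sol[p:]
        grad = np.zeros(c + 1)
        tr_pz = np.zeros(c)
        for i in range(c):
            ui = u[offsets[i]: offsets[i + 1]]
            # tr(Z_i' P Z_i) via the classical MME identity
            tr_pz[i] = (q_sizes[i] - (s2e / theta_[i]) * tr_blocks[i]) / theta_[i]
            quad = float(ui @ ui) / theta_[i] ** 2  # ||Z_i' P y||^2
            grad[i] = -0.5 * (tr_pz[i] - quad)
        tr_p = (n - p - float(np.dot(theta_[:c], tr_pz))) / s2e
        grad[-1] = -0.5 * (tr_p - float(py @ py))
        return grad, tr_pz, tr_blocks, py

    def em_step(theta_, sol, tr_blocks, e):
        s2e = theta_[-1]
        u = sol[p:]
        new = theta_.copy()
        for i in range(c):
            ui = u[offsets[i]: offsets[i + 1]]
            new[i] = (float(ui @ ui) + s2e * tr_blocks[i]) / q_sizes[i]
        new[-1] = float(y @ e) / (n - p)
        return np.maximum(new, floor)

    cf, sol, e, ll = factor_and_loglik(theta)
    n_iter = 0
    converged = False
    ai = None
    for n_iter in range(1, max_iter + 1):
        grad, tr_pz, tr_blocks, py = gradient_and_traces(cf, sol, e, theta)
        s2e = theta[-1]
        # average-information matrix over (components..., residual)
        fvecs = []
        for i in range(c):
            ui = sol[p:][offsets[i]: offsets[i + 1]]
            fvecs.append(zs[i] @ (ui / theta[i]))
        fvecs.append(py)
        pf = [p_apply(cf, f, s2e) for f in fvecs]
        ai = 0.5 * np.array(
            [[float(fvecs[i] @ pf[j]) for j in range(c + 1)] for i in range(c + 1)]
        )

        try:
            step = np.linalg.solve(ai, grad)
        except np.linalg.LinAlgError:
            step = None

        best = None
        if n_iter > n_em_warmup and step is not None:
            # projected AI step with step-halving on likelihood decrease
            for _ in range(5):
                cand = np.maximum(theta + step, floor)
                try:
                    out = factor_and_loglik(cand)
                except RemlError:
                    step = step / 2.0
                    continue
                if out[3] >= ll - 1e-10:
                    best = (cand, out)
                    break
                step = step / 2.0
        if best is None:
            cand = em_step(theta, sol, tr_blocks, e)
            best = (cand, factor_and_loglik(cand))
        proposal, (cf_new, sol_new, e_new, ll_new) = best

        delta = abs(ll_new - ll)
        param_change = np.max(
            np.abs(proposal - theta) / np.maximum(np.abs(theta), floor)
        )
        theta, cf, sol, e, ll = proposal, cf_new, sol_new, e_new, ll_new
        if delta < tol * (1.0 + abs(ll)) or param_change < 1e-7:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML did not reach tolerance in {max_iter} iterations "
            f"(last |dlogL|={delta:.2e})",
            RuntimeWarning,
        )

    boundary = [names[i] for i in range(c) if theta[i] <= 10 * floor]
    if boundary:
        warnings.warn(
            f"variance component(s) at boundary (~0): {boundary}", RuntimeWarning
        )

    # asymptotic covariance from the final AI matrix
    grad, tr_pz, tr_blocks, py = gradient_and_traces(cf, sol, e, theta)
    s2e = theta[-1]
    fvecs = []
    for i in range(c):
        ui = sol[p:][offsets[i]: offsets[i + 1]]
        fvecs.append(zs[i] @ (ui / theta[i]))
    fvecs.append(py)
    pf = [p_apply(cf, f, s2e) for f in fvecs]
    ai = 0.5 * np.array(
        [[float(fvecs[i] @ pf[j]) for j in range(c + 1)] for i in range(c + 1)]
    )
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ai)
        warnings.warn("AI matrix singular; covariance from pseudo-inverse",
                      RuntimeWarning)
    # symmetrize and project to PSD (boundary estimates can tip eigenvalues)
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    if w.min() < 0:
        cov = (v * np.maximum(w, 0.0)) @ v.T

    comp_names = names + ["residual"]
    components = dict(zip(comp_names, map(float, theta)))
    u_series = {
        names[i]: pd.Series(
            sol[p:][offsets[i]: offsets[i + 1]], index=level_names[i]
        )
        for i in range(c)
    }
    leverage = residuals = None
    if compute_leverage:
        cinv = linalg.cho_solve(cf, np.eye(p + q), check_finite=False)
        w_rows = sparse.hstack([sparse.csr_matrix(x), z_all], format="csr")
        # h_ii = w_i' C^-1 w_i, rows are sparse
        wc = w_rows @ cinv
        leverage = np.asarray(wc.multiply(w_rows).sum(axis=1)).ravel() \
            if sparse.issparse(wc) else np.einsum(
                "ij,ij->i", wc, w_rows.toarray())
        residuals = e
    return RemlResult(
        components=components,
        cov=pd.DataFrame(cov, index=comp_names, columns=comp_names),
        beta=sol[:p],
        u=u_series,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        boundary=boundary,
        leverage=leverage,
        residuals=residuals,
    )
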