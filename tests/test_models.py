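"""RR-BLUP and penalized-regression solvers against closed-form oracles."""

import numpy as np
import pytest

from switchgs.models import (GsFit, fit_penalized, fit_rrblup, lambda_path,
                             predict, select_lambda)


@pytest.fixture(scope="module")
def ridge_fixture():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(8, 3))
    y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.5, size=8)
    return x, y


class TestRrblup:
    def test_effects_equal_closed_form_ridge_at_reml_delta(self, ridge_fixture):
        x, y = ridge_fixture
        fit = fit_rrblup(x, y)
        u = np.linalg.solve(
            x.T @ x + fit.penalty * np.eye(3), x.T @ (y - fit.intercept)
        )
        assert np.allclose(fit.effects, u, atol=1e-6)

    def test_reml_delta_matches_grid_search(self, ridge_fixture):
        """1-D grid search of the dense restricted likelihood (oracle)."""
        x, y = ridge_fixture
        n = len(y)
        k = x @ x.T
        one = np.ones(n)

        def rll(delta):
            v = k + delta * np.eye(n)
            vi = np.linalg.inv(v)
            p = vi - np.outer(vi @ one, one @ vi) / (one @ vi @ one)
            s2u = (y @ p @ y) / (n - 1)
            _, ld = np.linalg.slogdet(v)
            return -0.5 * (ld + np.log(one @ vi @ one) + (n - 1) * np.log(s2u))

        grid = np.exp(np.linspace(-8, 6, 50_000))
        best = grid[np.argmax([rll(g) for g in grid])]
        fit = fit_rrblup(x, y)
        assert fit.penalty == pytest.approx(best, abs=1e-3)

    def test_null_signal_limit(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, (20, 10)).astype(float)
        y = 5.0 + rng.normal(scale=1e-6, size=20)
        fit = fit_rrblup(x, y)
        assert np.abs(fit.effects).max() < 1e-4
        assert fit.intercept == pytest.approx(5.0, abs=1e-3)

    def test_single_marker_recovery_noiseless(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 10))
        y = 2.0 * x[:, 3]
        fit = fit_rrblup(x, y)
        assert np.corrcoef(predict(fit, x), y)[0, 1] > 0.999
        assert np.argmax(np.abs(fit.effects)) == 3

    def test_effects_shrink_with_larger_delta(self, ridge_fixture):
        x, y = ridge_fixture
        fit = fit_rrblup(x, y)
        yc = y - fit.intercept
        norms = [
            np.linalg.norm(np.linalg.solve(x.T @ x + d * np.eye(3), x.T @ yc))
            for d in (0.01, 0.1, 1.0, 10.0)
        ]
        assert norms == sorted(norms, reverse=True)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_rrblup(np.ones((5, 2)), np.full(5, 3.0))


class TestPenalized:
    def test_soft_threshold_deadzone_exact_zero(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=60)
        z = (z - z.mean()) / z.std()
        y = 0.5 * z + rng.normal(size=60) * 0.3
        rho = abs(z @ (y - y.mean())) / 60
        fit = fit_penalized(z[:, None], y, alpha=1.0, lam=rho * 1.0001)
        assert fit.effects[0] == 0.0

    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 5))
        y = x @ rng.normal(size=5) + rng.normal(size=30) * 0.3
        fit = fit_penalized(x, y, alpha=1.0, lam=0.0)
        beta = np.linalg.lstsq(np.column_stack([np.ones(30), x]), y, rcond=None)[0]
        assert np.allclose(fit.effects, beta[1:], atol=1e-6)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_one_predictor_elastic_net_closed_form(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=50)
        z = (z - z.mean()) / z.std()
        y = 0.8 * z + rng.normal(size=50) * 0.2
        lam, a = 0.3, 0.5
        rho = float(z @ (y - y.mean())) / 50
        s = np.sign(rho) * max(abs(rho) - lam * a, 0.0)
        expected = s / (1.0 + lam * (1.0 - a))
        fit = fit_penalized(z[:, None], y, alpha=a, lam=lam)
        assert fit.effects[0] == pytest.approx(expected, abs=1e-8)

    def test_alpha_zero_matches_ridge_closed_form(self):
        """Elastic net at alpha=0 solves (Z'Z/n + lam I) b = Z'y/n."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        lam = 0.5
        z = (x - x.mean(0)) / x.std(0)
        yc = y - y.mean()
        b = np.linalg.solve(z.T @ z / 20 + lam * np.eye(50), z.T @ yc / 20)
        fit = fit_penalized(x, y, alpha=0.0, lam=lam)
        b_std = fit.effects * x.std(0)
        assert np.allclose(b_std, b, atol=1e-4)

    def test_lasso_support_monotone_along_path(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(40, 30))
        y = x[:, :5] @ rng.normal(size=5) + rng.normal(size=40) * 0.5
        z = (x - x.mean(0)) / x.std(0)
        path = lambda_path(z, y, 1.0, n_lambda=15)
        supports = [
            int(np.sum(fit_penalized(x, y, 1.0, lam).effects != 0))
            for lam in path
        ]
        assert supports == sorted(supports)  # path is decreasing in lambda

    def test_intercept_absorbs_constant_shift(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 10))
        y = x[:, 0] + rng.normal(size=25) * 0.2
        for fit_fn in (
            lambda yy: fit_rrblup(x, yy),
            lambda yy: fit_penalized(x, yy, 1.0, 0.05),
            lambda yy: fit_penalized(x, yy, 0.5, 0.05),
        ):
            f0, f1 = fit_fn(y), fit_fn(y + 100.0)
            assert np.allclose(f0.effects, f1.effects, atol=1e-6)
            assert f1.intercept - f0.intercept == pytest.approx(100.0, abs=1e-5)

    def test_zero_variance_marker_gets_zero_effect(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 4))
        x[:, 2] = 1.5
        y = rng.normal(size=20)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fit = fit_penalized(x, y, 1.0, 0.1)
        assert fit.effects[2] == 0.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_penalized(np.ones((4, 2)), np.arange(4.0), alpha=1.5, lam=0.1)


class TestSelectLambda:
    def test_pure_noise_selects_strong_penalty(self):
        """With no signal the chosen penalty should zero out nearly all
        effects (median over seeds)."""
        rng = np.random.default_rng(10)
        frac_nonzero = []
        for seed in range(10):
            x = rng.normal(size=(60, 100))
            y = rng.normal(size=60)
            lam = select_lambda(x, y, 1.0, rng_seed=seed)
            fit = fit_penalized(x, y, 1.0, lam)
            frac_nonzero.append(np.mean(fit.effects != 0))
        assert np.median(frac_nonzero) <= 0.05

    def test_signal_beats_path_endpoints(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(200, 500))
        y = x[:, :10] @ rng.normal(size=10) + rng.normal(size=200)

        def inner_mse(lam, seed=3):
            perm = np.random.default_rng(seed).permutation(200)
            folds = np.array_split(perm, 5)
            errs = []
            for val in folds:
                tr = np.setdiff1d(perm, val)
                fit = fit_penalized(x[tr], y[tr], 1.0, lam)
                errs.append(np.mean((predict(fit, x[val]) - y[val]) ** 2))
            return np.mean(errs)

        z = (x - x.mean(0)) / x.std(0)
        path = lambda_path(z, y, 1.0)
        lam = select_lambda(x, y, 1.0, rng_seed=3)
        assert inner_mse(lam) <= inner_mse(path[0])
        assert inner_mse(lam) <= inner_mse(path[-1])

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(50, 40))
        y = rng.normal(size=50)
        assert select_lambda(x, y, 0.5, rng_seed=5) == select_lambda(
            x, y, 0.5, rng_seed=5
        )

    def test_constant_response_degenerate_path(self):
        with pytest.raises(ValueError):
            select_lambda(np.random.default_rng(0).normal(size=(20, 5)),
                          np.full(20, 2.0), 1.0)


class TestPredict:
    def test_all_zero_effects_constant_prediction(self):
        fit = GsFit("lasso", intercept=3.0, effects=np.zeros(4),
                    marker_ids=list("abcd"), penalty=1.0, mixing=1.0)
        assert np.allclose(predict(fit, np.ones((5, 4))), 3.0)

    def test_linearity_in_dosage(self):
        fit = GsFit("rrblup", intercept=0.0, effects=np.array([2.0, -1.0]),
                    marker_ids=["a", "b"])
        x = np.array([[1.0, 1.0]])
        x2 = np.array([[2.0, 1.0]])
        assert predict(fit, x2)[0] - predict(fit, x)[0] == pytest.approx(2.0)

    def test_marker_mismatch_rejected(self):
        fit = GsFit("rrblup", intercept=0.0, effects=np.zeros(2),
                    marker_ids=["a", "b"])
        with pytest.raises(ValueError):
            predict(fit, np.ones((3, 2)), marker_ids=["a", "c"])
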