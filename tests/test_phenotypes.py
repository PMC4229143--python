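"""Outlier screening, trial REML / BLUPs, repeatability, Box-Cox."""

import shutil
import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from switchgs.phenotypes import (VarComp, boxcox_optimal, clone_mean_repeatability,
                                 fit_blup_model, flag_outliers, prepare_trait,
                                 repeatability_se, validate_trial_table)
from switchgs.reml import reml_fit
from switchgs.simulate import SimConfig, simulate_panel


def trial_from_model(n_geno=50, n_pop=10, years=(2009, 2010), blocks=("B1", "B2"),
                     s2g=1.0, s2gy=0.25, s2e=0.5, seed=0, mu=10.0):
    """Plot records drawn exactly from the trial variance-components model."""
    rng = np.random.default_rng(seed)
    genos = [f"g{i}" for i in range(n_geno)]
    pops = {g: f"p{i % n_pop}" for i, g in enumerate(genos)}
    g_eff = rng.normal(0, np.sqrt(s2g), n_geno)
    y_eff = rng.normal(0, 0.3, len(years))
    b_eff = rng.normal(0, 0.2, (len(years), len(blocks)))
    gy_eff = rng.normal(0, np.sqrt(s2gy), (n_geno, len(years)))
    rec = []
    for yi, yr in enumerate(years):
        for bi, bl in enumerate(blocks):
            eps = rng.normal(0, np.sqrt(s2e), n_geno)
            for gi, g in enumerate(genos):
                rec.append((g, pops[g], yr, "F1", bl, "t",
                            mu + y_eff[yi] + b_eff[yi, bi] + g_eff[gi]
                            + gy_eff[gi, yi] + eps[gi]))
    table = pd.DataFrame(rec, columns=[
        "genotype_id", "population_id", "year", "field_id", "block_id",
        "trait", "value"])
    return table, pd.Series(g_eff, index=genos)


class TestValidation:
    def test_genotype_in_two_populations_rejected(self):
        t, _ = trial_from_model(n_geno=10)
        t.loc[t.index[-1], "population_id"] = "other"
        with pytest.raises(ValueError, match="multiple populations"):
            validate_trial_table(t)

    def test_duplicate_plot_record_rejected(self):
        t, _ = trial_from_model(n_geno=10)
        with pytest.raises(ValueError, match="duplicate"):
            validate_trial_table(pd.concat([t, t.iloc[[0]]]))


class TestOutliers:
    def test_null_flag_rate_below_one_percent(self):
        t, _ = trial_from_model(n_geno=125, n_pop=25, seed=1)  # 1000 records
        flagged = flag_outliers(t, "t", cutoff=4.0)
        assert len(flagged) / len(t) < 0.01

    def test_planted_outlier_recovered(self):
        t, _ = trial_from_model(n_geno=60, seed=2, s2e=0.5)
        i = t.index[37]
        t.loc[i, "value"] += 10 * np.sqrt(0.5)
        flagged = flag_outliers(t, "t", cutoff=4.0)
        assert i in flagged

    def test_empty_trait_is_error(self):
        t, _ = trial_from_model(n_geno=10)
        t["value"] = np.nan
        with pytest.raises(ValueError):
            flag_outliers(t, "t")


class TestRemlFit:
    def test_tiny_balanced_case_beats_grid_search_oracle(self):
        """The REML optimum's restricted likelihood is >= a dense grid search
        of the restricted log-likelihood (evaluated independently)."""
        t, _ = trial_from_model(n_geno=4, n_pop=4, seed=3)
        vc, blups, res = fit_blup_model(t, "t")
        sub = t
        y = sub["value"].to_numpy()
        n = len(y)
        x = np.ones((n, 1))
        zs = {}
        for name, lab in [
            ("genotype", sub["genotype_id"]),
            ("genotype_x_year", sub["genotype_id"].astype(str) + "@" + sub["year"].astype(str)),
            ("year", sub["year"]),
            ("block_in_year", sub["year"].astype(str) + "/" + sub["block_id"].astype(str)),
        ]:
            zs[name] = pd.get_dummies(lab).to_numpy(dtype=float)

        def dense_rll(theta):
            v = theta[-1] * np.eye(n)
            for th, z in zip(theta[:-1], zs.values()):
                v += th * (z @ z.T)
            vi = np.linalg.inv(v)
            xvx = x.T @ vi @ x
            p = vi - vi @ x @ np.linalg.inv(xvx) @ x.T @ vi
            s1, ld = np.linalg.slogdet(v)
            s2, ldx = np.linalg.slogdet(xvx)
            return -0.5 * (ld + ldx + y @ p @ y)

        fitted = np.array([vc.components[k] for k in zs] + [vc.components["residual"]])
        # internal and dense objectives agree at the optimum
        assert dense_rll(fitted) == pytest.approx(res.loglik, abs=1e-6)
        grid = np.array([0.05, 0.2, 0.5, 1.0, 2.0])
        best = -np.inf
        for a in grid:
            for b in grid:
                for c in grid:
                    for d in grid:
                        for e in grid:
                            best = max(best, dense_rll(np.array([a, b, c, d, e])))
        assert res.loglik >= best - 1e-4

    def test_matches_lme4_variance_components(self, tmp_path):
        """Independent oracle: lme4's REML on the same crossed layout."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        t, _ = trial_from_model(n_geno=40, n_pop=8, years=(2009, 2010, 2011), seed=4)
        vc, _, res = fit_blup_model(t, "t")
        csv = tmp_path / "d.csv"
        t.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$by <- interaction(d$year, d$block_id)
            d$gy <- interaction(d$genotype_id, d$year)
            f <- lmer(value ~ 1 + (1|genotype_id) + (1|gy) + (1|year) + (1|by),
                      data=d, REML=TRUE)
            v <- as.data.frame(VarCorr(f))
            for (i in seq_len(nrow(v))) cat(v$grp[i], v$vcov[i], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout
        ref = {}
        key = {"genotype_id": "genotype", "gy": "genotype_x_year",
               "year": "year", "by": "block_in_year", "Residual": "residual"}
        for line in out.strip().splitlines():
            grp, val = line.split()
            ref[key[grp]] = float(val)
        for name, val in ref.items():
            assert vc.components[name] == pytest.approx(val, rel=2e-3, abs=1e-4)

    def test_noiseless_blups_match_true_genotype_values(self):
        t, g_true = trial_from_model(s2gy=0.0, s2e=1e-8, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc, blups, _ = fit_blup_model(t, "t")
        r = np.corrcoef(blups.loc[g_true.index], g_true)[0, 1]
        assert r > 0.999

    def test_blups_shrink_relative_to_raw_means(self):
        t, _ = trial_from_model(s2e=2.0, seed=6)
        vc, blups, _ = fit_blup_model(t, "t")
        raw = t.groupby("genotype_id")["value"].mean()
        assert blups.var() < raw.var()

    def test_single_year_single_block_rejected(self):
        t, _ = trial_from_model(years=(2009,), blocks=("B1",))
        with pytest.raises(ValueError):
            fit_blup_model(t, "t")


class TestRepeatability:
    def make_vc(self, s2g, s2gy, s2e, y=3, r=2, cov=None):
        comps = {"genotype": s2g, "genotype_x_year": s2gy, "residual": s2e}
        names = list(comps)
        c = pd.DataFrame(np.zeros((3, 3)) if cov is None else cov,
                         index=names, columns=names)
        return VarComp(components=comps, asymptotic_covariance=c,
                       n_years=y, n_reps=r)

    @pytest.mark.parametrize("s2g, s2gy, s2e, y, r, expected", [
        (1.0, 0.0, 0.0, 3, 2, 1.0),
        (1.0, 1.0, 1.0, 3, 2, 1 / (1 + 1/3 + 1/6)),
        (0.0, 0.0, 1.0, 3, 2, 0.0),
    ])
    def test_formula(self, s2g, s2gy, s2e, y, r, expected):
        vc = self.make_vc(s2g, s2gy, s2e, y, r)
        assert clone_mean_repeatability(vc) == pytest.approx(expected, abs=1e-9)

    def test_undefined_when_all_zero(self):
        with pytest.raises(ValueError):
            clone_mean_repeatability(self.make_vc(0, 0, 0))

    def test_monotone_in_components(self):
        h = [clone_mean_repeatability(self.make_vc(g, 0.5, 1.0))
             for g in (0.2, 0.5, 1.0, 2.0)]
        assert h == sorted(h)
        h2 = [clone_mean_repeatability(self.make_vc(1.0, 0.5, e))
              for e in (0.1, 0.5, 2.0, 5.0)]
        assert h2 == sorted(h2, reverse=True)

    def test_se_zero_covariance(self):
        vc = self.make_vc(1.0, 0.5, 0.5)
        assert repeatability_se(vc) == 0.0

    def test_se_matches_finite_difference_gradient(self):
        cov = np.diag([0.04, 0.01, 0.02])
        vc = self.make_vc(1.0, 0.5, 0.8, cov=cov)
        names = ["genotype", "genotype_x_year", "residual"]

        def h_of(vals):
            return clone_mean_repeatability(self.make_vc(*vals))

        base = np.array([1.0, 0.5, 0.8])
        eps = 1e-7
        grad = np.array([
            (h_of(base + eps * np.eye(3)[i]) - h_of(base - eps * np.eye(3)[i]))
            / (2 * eps)
            for i in range(3)
        ])
        expected = float(np.sqrt(grad @ cov @ grad))
        assert repeatability_se(vc) == pytest.approx(expected, abs=1e-6)

    def test_non_psd_covariance_rejected(self):
        cov = np.array([[1, 2, 0], [2, 1, 0], [0, 0, 1]], dtype=float)
        vc = self.make_vc(1.0, 0.5, 0.8, cov=cov)
        with pytest.raises(ValueError, match="semi-definite"):
            repeatability_se(vc)


class TestBoxCox:
    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(50, 5, 500)
        lam, _ = boxcox_optimal(x)
        assert 0.7 <= lam <= 1.3

    def test_lognormal_data_lambda_near_zero(self):
        rng = np.random.default_rng(9)
        x = np.exp(rng.normal(0, 0.5, 500))
        lam, _ = boxcox_optimal(x)
        assert -0.15 <= lam <= 0.15

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            boxcox_optimal(np.full(10, 3.0))

    def test_nonpositive_requires_shift(self):
        x = np.array([-1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            boxcox_optimal(x)
        lam, out = boxcox_optimal(x, shift=True)
        assert np.isfinite(out).all()


class TestEndToEnd:
    def test_simulated_repeatability_recovered(self, small_panel):
        cfg, matrix, pop_of, trial, truth = small_panel
        s = prepare_trait(trial, "t1")
        assert abs(s.repeatability - truth.realized_h2) < 0.12
        assert 0.0 < s.repeatability_se < 0.1
        assert set(s.blups.index) <= set(matrix.samples)
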