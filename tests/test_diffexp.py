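"""Moderated linear model: OLS against hand computation, moment estimator
against its generating model, BH against the step-up definition, and the whole
chain against an independent R/limma run on a small matrix."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foxodep import (
    CONTRASTS,
    adjust_bh,
    contrast_test,
    fit_group_means,
    moderate_variances,
    run_contrasts,
)
from foxodep.diffexp import GroupFit, ModerationFit
from tests.conftest import matrix_from_values


class TestFit:
    def test_constant_groups(self):
        mat = matrix_from_values([[1.0] * 8], ["A", "A", "B", "B", "C", "C", "D", "D"])
        fit = fit_group_means(mat)
        assert (fit.means.iloc[0] == 1.0).all()
        assert fit.s2.iloc[0] == 0.0
        assert fit.df == 4

    def test_hand_ols(self):
        # A = {0, 2}, other groups {0, 0}: mean_A = 1, pooled s^2 = 2/4 = 0.5
        mat = matrix_from_values([[0, 2, 0, 0, 0, 0, 0, 0]], ["A", "A", "B", "B", "C", "C", "D", "D"])
        fit = fit_group_means(mat)
        assert fit.means.loc[:, "A"].iloc[0] == 1.0
        assert fit.s2.iloc[0] == pytest.approx(0.5)

    def test_order_invariance(self, rng):
        values = rng.normal(30, 1, size=(40, 24))
        genos = ["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6
        mat = matrix_from_values(values, genos)
        perm_rows = rng.permutation(40)
        perm_cols = rng.permutation(24)
        shuffled = matrix_from_values(values[perm_rows][:, perm_cols], [genos[j] for j in perm_cols])
        res = run_contrasts(mat)["CvsA"]
        res_shuffled = run_contrasts(shuffled)["CvsA"]
        orig_ids = [f"P{i:05d}" for i in perm_rows]
        np.testing.assert_allclose(
            res.loc[orig_ids, "t"].to_numpy(), res_shuffled["t"].to_numpy(), rtol=1e-10
        )

    def test_missing_values_rejected(self):
        values = np.full((2, 8), 1.0)
        values[0, 0] = np.nan
        mat = matrix_from_values(values, ["A", "A", "B", "B", "C", "C", "D", "D"])
        with pytest.raises(ValueError, match="missing"):
            fit_group_means(mat)


class TestModeration:
    def test_identical_variances_give_infinite_prior_df(self):
        fit = moderate_variances(np.full(100, 0.04), 20.0)
        assert np.isinf(fit.prior_df)
        assert fit.prior_var == pytest.approx(0.04)
        assert np.allclose(fit.posterior_var, 0.04)

    def test_scale_equivariance(self, rng):
        s2 = stats.chi2.rvs(10, size=500, random_state=1) / 10 * 0.01
        a = moderate_variances(s2, 10.0)
        b = moderate_variances(2 * s2, 10.0)
        assert b.prior_df == pytest.approx(a.prior_df, rel=1e-9)
        assert b.prior_var == pytest.approx(2 * a.prior_var, rel=1e-9)

    def test_parameter_recovery_from_hierarchical_model(self):
        # sigma_g^2 ~ d0 s0^2 / chi2_{d0}; s_g^2 | sigma^2 ~ sigma^2 chi2_dg / dg
        rng = np.random.default_rng(0)
        d0, s02, dg, n = 4.0, 0.0025, 20.0, 5000
        sigma2 = d0 * s02 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        fit = moderate_variances(s2, dg)
        assert abs(fit.prior_df - d0) <= 1.0
        assert abs(fit.prior_var - s02) / s02 <= 0.10

    def test_posterior_is_precision_weighted_blend(self, rng):
        s2 = stats.f.rvs(20, 4, size=300, random_state=2) * 0.01
        fit = moderate_variances(s2, 20.0)
        expected = (fit.prior_df * fit.prior_var + 20.0 * s2) / (fit.prior_df + 20.0)
        np.testing.assert_allclose(fit.posterior_var, expected)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="zero"):
            moderate_variances(np.zeros(10), 20.0)


def _manual_fit(estimates, post_var, n_per_group, df):
    means = pd.DataFrame(
        {"A": np.zeros(len(estimates)), "B": 0.0, "C": estimates, "D": 0.0},
        index=[f"P{i}" for i in range(len(estimates))],
    )
    n = pd.Series({g: n_per_group for g in "ABCD"})
    fit = GroupFit(means=means, n=n, s2=pd.Series(post_var, index=means.index), df=df)
    return fit


class TestContrast:
    def test_zero_estimate(self):
        fit = _manual_fit([0.0], [0.04], 4, 12.0)
        mod = ModerationFit(4.0, 0.04, fit.s2)
        res = contrast_test(fit, mod, "CvsA")
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert res["ci_low"].iloc[0] == pytest.approx(-res["ci_high"].iloc[0])

    def test_normal_limit_closed_form(self):
        # estimate 1.0, SE 0.25, infinite df: CI = 1 +/- 1.95996 * 0.25
        fit = _manual_fit([1.0], [0.125], 4, 12.0)
        mod = ModerationFit(np.inf, 0.125, fit.s2)
        res = contrast_test(fit, mod, "CvsA")
        assert res["se"].iloc[0] == pytest.approx(0.25)
        assert res["ci_low"].iloc[0] == pytest.approx(0.51, abs=0.005)
        assert res["ci_high"].iloc[0] == pytest.approx(1.49, abs=0.005)
        assert res["p"].iloc[0] < 1e-4

    def test_interaction_is_linear_in_means(self, rng):
        values = rng.normal(30, 1, size=(30, 24))
        mat = matrix_from_values(values, ["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6)
        fit = fit_group_means(mat)
        mod = moderate_variances(fit.s2, fit.df)
        res = contrast_test(fit, mod, "interaction")
        expected = (fit.means["C"] - fit.means["A"]) - (fit.means["D"] - fit.means["B"])
        np.testing.assert_allclose(res["estimate"], expected)

    def test_zero_se_convention(self):
        fit = _manual_fit([1.0, 0.0], [0.0, 0.0], 4, 12.0)
        mod = ModerationFit(0.5, 0.0, fit.s2)
        res = contrast_test(fit, mod, "CvsA")
        assert res["zero_se"].all()
        assert res["p"].tolist() == [0.0, 1.0]

    def test_prior_df_limits(self, rng):
        values = rng.normal(30, 0.5, size=(50, 24))
        mat = matrix_from_values(values, ["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6)
        fit = fit_group_means(mat)
        # d0 -> 0: moderated t equals the ordinary per-protein t
        res0 = contrast_test(fit, ModerationFit(0.0, 1.0, fit.s2), "CvsA")
        ordinary = (fit.means["C"] - fit.means["A"]) / np.sqrt(fit.s2 * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(res0["t"], ordinary)
        # d0 -> inf: moderated t equals the pooled-variance t
        pooled = float(fit.s2.mean())
        resinf = contrast_test(
            fit, ModerationFit(np.inf, pooled, pd.Series(pooled, index=fit.s2.index)), "CvsA"
        )
        pooled_t = (fit.means["C"] - fit.means["A"]) / np.sqrt(pooled * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(resinf["t"], pooled_t)


class TestBH:
    @staticmethod
    def _brute_force(p):
        # literal step-up definition: adj_i = min over j >= rank(i) of m * p_(j) / j
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        for pos, idx in enumerate(order):
            adj[idx] = min(min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0)
        return adj

    def test_textbook_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(adjust_bh(p), self._brute_force(p))

    def test_ties_all_equal_and_single(self):
        np.testing.assert_allclose(adjust_bh([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(adjust_bh([0.123]), [0.123])

    def test_nan_propagated_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            out = adjust_bh([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], self._brute_force([0.01, 0.04]))

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


R_SNIPPET = """
suppressMessages(library(limma))
x <- as.matrix(read.delim("{matrix}", row.names = 1))
group <- factor(rep(c("A", "B", "C", "D"), each = 3), levels = c("A", "B", "C", "D"))
design <- model.matrix(~0 + group)
colnames(design) <- levels(group)
fit <- lmFit(x, design)
cm <- makeContrasts(CvsA = C - A, levels = design)
fit2 <- eBayes(contrasts.fit(fit, cm))
out <- list(d0 = fit2$df.prior, s02 = fit2$s2.prior,
            t = as.numeric(fit2$t[, "CvsA"]), p = as.numeric(fit2$p.value[, "CvsA"]))
cat(jsonlite::toJSON(out, digits = 12, auto_unbox = TRUE))
"""


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_moderated_t_matches_limma(tmp_path, rng):
    """Dual-route check of the whole moderated-t chain against R/limma."""
    values = rng.normal(28, 1, size=(60, 12))
    values[:10, 6:9] += 1.0  # some real C-vs-A signal
    genos = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
    mat = matrix_from_values(values, genos)
    mat.values.to_csv(tmp_path / "m.tsv", sep="\t")
    script = tmp_path / "limma_check.R"
    script.write_text(R_SNIPPET.format(matrix=str(tmp_path / "m.tsv")))
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
    )
    ref = json.loads(proc.stdout)

    fit = fit_group_means(mat)
    mod = moderate_variances(fit.s2, fit.df)
    res = contrast_test(fit, mod, "CvsA")
    assert mod.prior_df == pytest.approx(ref["d0"], rel=1e-4)
    assert mod.prior_var == pytest.approx(ref["s02"], rel=1e-4)
    np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6, atol=1e-12)
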