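"""NB GLM differential-abundance engine: fits, dispersion, LRT, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from cystmir.diffexpr import (
    NBGLMDifferentialExpression,
    adjust_fdr,
    build_design,
    estimate_dispersion,
    fit_glm,
    fold_report,
    lrt_test,
)
from tests.conftest import nb_counts


class TestFitGlm:
    def test_matches_statsmodels_nb_fit(self, two_group_design):
        rng = np.random.default_rng(0)
        X = two_group_design
        offset = np.log(rng.uniform(5e4, 2e5, X.shape[0]))
        mu = np.exp(offset + 0.5 * X[:, 1] + np.log(5e-4))
        y = rng.negative_binomial(5, 5 / (5 + mu))[None, :]
        fit = fit_glm(y, X, 0.2, offset)
        ref = sm.GLM(
            y[0], X, family=sm.families.NegativeBinomial(alpha=0.2), offset=offset
        ).fit()
        assert np.allclose(fit["beta"][0], ref.params, atol=1e-6)
        assert fit["loglik"][0] == pytest.approx(ref.llf, abs=1e-6)

    def test_identical_cpm_gives_zero_log2fc(self, two_group_design):
        X = two_group_design
        totals = np.array([1000.0, 2000.0] * 10)
        y = (totals * 0.05)[None, :]  # constant CPM across all samples
        fit = fit_glm(y, X, 0.1, np.log(totals))
        assert fit["beta"][0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_exact_twofold_cpm_gives_log2fc_one(self, two_group_design):
        X = two_group_design
        totals = np.full(20, 1000.0)
        y = np.where(X[:, 1] == 1, 100.0, 50.0)[None, :]
        fit = fit_glm(y, X, 0.0, np.log(totals))
        assert fit["beta"][0, 1] / np.log(2) == pytest.approx(1.0, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_glm(np.ones((1, 6)), X, 0.1)


class TestDispersion:
    def test_poisson_counts_give_near_zero_common(self, two_group_design):
        rng = np.random.default_rng(1)
        X = two_group_design
        lib = rng.uniform(5e4, 2e5, 20)
        q = rng.lognormal(0, 1.5, 200)
        q /= q.sum()
        y = nb_counts(rng, q, lib, np.zeros(200), 0, X[:, 1])
        est = estimate_dispersion(y, X, np.log(lib))
        assert est["common"] < 0.05

    def test_nb_dispersion_recovered(self, two_group_design):
        X = two_group_design
        lib = np.full(20, 1e5)
        estimates = []
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            q = rng.lognormal(0, 1.0, 100)
            q /= q.sum()
            y = nb_counts(rng, q, lib, np.zeros(100), 0.3, X[:, 1])
            estimates.append(estimate_dispersion(y, X, np.log(lib))["common"])
        assert abs(np.mean(estimates) / 0.3 - 1.0) < 0.3

    def test_single_unit_falls_back_with_warning(self, two_group_design):
        rng = np.random.default_rng(2)
        y = rng.poisson(50.0, size=(1, 20))
        with pytest.warns(UserWarning, match="common-only"):
            est = estimate_dispersion(y, two_group_design, np.zeros(20))
        assert est["tagwise"].shape == (1,)
        assert est["tagwise"][0] == est["common"]


class TestLrt:
    def test_identical_fits_give_p_one(self, two_group_design):
        rng = np.random.default_rng(3)
        y = rng.poisson(50.0, size=(5, 20))
        full = fit_glm(y, two_group_design, 0.1)
        fake_reduced = {"beta": full["beta"][:, :1], "loglik": full["loglik"]}
        p, stat = lrt_test(full, fake_reduced)
        assert np.allclose(stat, 0.0) and np.allclose(p, 1.0)

    def test_non_nested_rejected(self, two_group_design):
        rng = np.random.default_rng(4)
        y = rng.poisson(50.0, size=(2, 20))
        full = fit_glm(y, two_group_design, 0.1)
        with pytest.raises(ValueError, match="nested"):
            lrt_test(full, full)

    def test_poisson_limit_matches_poisson_glm_oracle(self, two_group_design):
        # phi = 0: the NB LRT must equal a Poisson-GLM LRT on the same data
        rng = np.random.default_rng(5)
        X = two_group_design
        offset = np.log(rng.uniform(5e4, 2e5, 20))
        mu = np.exp(offset + np.log(2e-4) + 0.7 * X[:, 1])
        y = rng.poisson(mu)[None, :]
        full = fit_glm(y, X, 0.0, offset)
        red = fit_glm(y, X[:, :1], 0.0, offset)
        _, stat = lrt_test(full, red)
        ofull = sm.GLM(y[0], X, family=sm.families.Poisson(), offset=offset).fit()
        ored = sm.GLM(y[0], X[:, :1], family=sm.families.Poisson(), offset=offset).fit()
        assert stat[0] == pytest.approx(2 * (ofull.llf - ored.llf), abs=1e-6)


class TestAdjustFdr:
    def test_bh_closed_form(self):
        fdr, sig = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(fdr, 0.04)
        assert sig.all()

    def test_single_p(self):
        fdr, sig = adjust_fdr([0.03])
        assert fdr[0] == pytest.approx(0.03) and sig[0]

    def test_empty_input(self):
        fdr, sig = adjust_fdr([])
        assert len(fdr) == 0 and len(sig) == 0

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        fdr, _ = adjust_fdr(p)
        ref = sm.stats.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(fdr, ref)

    def test_null_uniform_yields_no_flags(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=1000)
        _, sig = adjust_fdr(p)
        assert sig.sum() <= 2  # ~0 expected with no planted effects

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
    def test_permutation_invariant(self, pvals, rnd):
        p = np.array(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        fdr, _ = adjust_fdr(p)
        fdr_perm, _ = adjust_fdr(p[perm])
        assert np.allclose(fdr[perm], fdr_perm)


class TestFoldReport:
    @pytest.mark.parametrize(
        "log2fc,fold,direction",
        [
            (3.2, 9.2, "up"),
            (1.2, 2.3, "up"),
            (3.6, 12.1, "up"),
            (-4.3, 19.7, "down"),
            (-4.4, 21.1, "down"),
            (-1.6, 3.0, "down"),
            (0.0, 1.0, "none"),
        ],
    )
    def test_linear_fold_with_direction(self, log2fc, fold, direction):
        assert fold_report(log2fc) == (fold, direction)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_report(np.nan)


class TestDesign:
    def test_sex_dropped_when_uninformative(self):
        groups = ["A"] * 4 + ["B"] * 4
        sex = ["M"] * 4 + ["M", "M", "F", "F"]  # no F in group A
        with pytest.warns(UserWarning, match="sex covariate dropped"):
            X, names, _ = build_design(groups, sex)
        assert names == ["intercept", "group"]

    def test_sex_included_when_informative(self):
        groups = ["A", "A", "B", "B"]
        sex = ["M", "F", "M", "F"]
        X, names, _ = build_design(groups, sex)
        assert names == ["intercept", "group", "sex"]

    def test_needs_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            build_design(["A", "A", "A"])


class TestEstimator:
    def test_all_zero_unit_reported_flagged(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(
            rng.poisson(200, size=(5, 8)),
            index=[f"u{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        mat.loc["u0"] = 0
        model = NBGLMDifferentialExpression(min_cpm=0.0).fit(
            mat, ["A"] * 4 + ["B"] * 4
        )
        row = model.results_.loc["u0"]
        assert row["p_value"] == 1.0 and np.isnan(row["log2_fc"])

    def test_significance_rule_joint(self):
        # significant iff p < 0.05 AND fdr < 0.2
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(
            rng.poisson(100, size=(30, 12)),
            index=[f"u{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(12)],
        )
        mat.iloc[0, 6:] *= 6  # one strong effect
        model = NBGLMDifferentialExpression().fit(mat, ["A"] * 6 + ["B"] * 6)
        res = model.results_
        expected = (res["p_value"] < 0.05) & (res["fdr"] < 0.2)
        assert (res["significant"] == expected).all()

    def test_sklearn_params_roundtrip(self):
        model = NBGLMDifferentialExpression(min_cpm=2.0)
        clone = NBGLMDifferentialExpression(**model.get_params())
        assert clone.get_params() == model.get_params()
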