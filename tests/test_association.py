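"""Logistic fitting, SNP models, BH FDR, sensitivity and interaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import haplocc as h
from haplocc.association import (AliasingWarning, ModelError, build_design,
                                 fit_logistic)

from conftest import make_gm, make_subjects


def _two_by_two_data(a, b, c, d):
    """cases: a exposed / b unexposed; controls: c exposed / d unexposed."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = pd.DataFrame({"const": np.ones_like(y), "exposed": x})
    return y, X


class TestFitLogistic:
    def test_balanced_intercept_only(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        fit = fit_logistic(y, pd.DataFrame({"const": np.ones(20)}))
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)
        assert np.exp(fit.params["const"]) == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        y, X = _two_by_two_data(30, 70, 20, 80)
        fit = fit_logistic(y, X)
        assert np.exp(fit.params["exposed"]) == pytest.approx(
            (30 * 80) / (70 * 20), rel=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 400
        X = pd.DataFrame({"const": 1.0, "x1": rng.normal(size=n),
                          "x2": rng.binomial(1, 0.3, n).astype(float)})
        eta = -0.2 + 0.6 * X["x1"] - 0.4 * X["x2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X.to_numpy()).fit(disp=0)
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-8)
        np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, atol=1e-8)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_coefficient_recovery_at_large_n(self):
        rng = np.random.default_rng(4)
        n = 5000
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n)})
        beta = np.array([-0.5, 0.8])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X.to_numpy() @ beta)))).astype(float)
        fit = fit_logistic(y, X)
        for b, name in zip(beta, X.columns):
            assert abs(fit.params[name] - b) < 3 * fit.bse[name]

    def test_aliased_column_dropped_with_warning(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        x = np.tile([0.0, 1.0], 30)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": x})
        with pytest.warns(AliasingWarning):
            fit = fit_logistic(y, X)
        assert len(fit.dropped) == 1

    def test_complete_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        X = pd.DataFrame({"const": 1.0, "x": y.copy()})
        fit = fit_logistic(y, X)
        assert not fit.converged
        assert "x" in fit.separated
        assert np.isnan(fit.params["x"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_binary_exposure_equals_log_cross_product_ratio(self, cells):
        a, b, c, d = cells
        y, X = _two_by_two_data(a, b, c, d)
        fit = fit_logistic(y, X)
        assert fit.params["exposed"] == pytest.approx(
            np.log(a * d / (b * c)), abs=1e-6)


class TestSnpModels:
    def _cohort(self, beta, n=4000, maf=0.3, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, maf, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.4 + beta * g)))).astype(int)
        gm = make_gm(g.reshape(-1, 1), rsids=["rsX"])
        return gm, make_subjects(y)

    def test_trend_recovers_per_allele_or(self):
        gm, subjects = self._cohort(np.log(1.5), n=10_000, seed=1)
        _, trend = h.snp_models(gm, subjects, "rsX", covariates=())
        assert 1.4 <= trend.terms["OR"].iloc[0] <= 1.6

    def test_null_snp_ci_covers_one(self):
        gm, subjects = self._cohort(0.0, seed=2)
        _, trend = h.snp_models(gm, subjects, "rsX", covariates=())
        row = trend.terms.iloc[0]
        assert row["lcl"] <= 1.0 <= row["ucl"]

    def test_monomorphic_raises_naming_rsid(self):
        gm = make_gm(np.zeros((30, 1), dtype=np.int8), rsids=["rsMono"])
        with pytest.raises(ModelError, match="rsMono"):
            h.snp_models(gm, make_subjects([1] * 15 + [0] * 15), "rsMono")

    def test_codominant_omits_hom_term_when_absent(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(1, 0.3, 300)        # only 0/1 genotypes
        gm = make_gm(g.reshape(-1, 1), rsids=["rsD"])
        codom, trend = h.snp_models(gm, make_subjects(rng.integers(0, 2, 300)),
                                    "rsD", covariates=())
        assert list(codom.terms["term"]) == ["rsD_het"]
        assert np.isfinite(trend.trend_p)

    def test_trend_reproduces_multiplicative_codominant_pattern(self):
        # when codominant ORs are exactly (1, r, r^2) the per-allele OR is r
        r = 1.6
        counts = {0: (400, 400), 1: (int(400 * r), 400), 2: (int(400 * r * r), 400)}
        g, y = [], []
        for geno, (ncase, nctrl) in counts.items():
            g += [geno] * (ncase + nctrl)
            y += [1] * ncase + [0] * nctrl
        gm = make_gm(np.array(g).reshape(-1, 1), rsids=["rsR"])
        _, trend = h.snp_models(gm, make_subjects(y), "rsR", covariates=())
        assert trend.terms["OR"].iloc[0] == pytest.approx(
            counts[1][0] / 400, rel=0.01)


class TestJointModel:
    def test_independent_snps_joint_close_to_marginal(self):
        rng = np.random.default_rng(6)
        n = 4000
        g1, g2 = rng.binomial(2, 0.3, n), rng.binomial(2, 0.25, n)
        eta = -0.5 + 0.35 * g1 + 0.30 * g2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_gm(np.column_stack([g1, g2]), rsids=["rA", "rB"])
        subjects = make_subjects(y)
        joint = h.joint_snp_model(gm, subjects, ["rA", "rB"], covariates=())
        _, mA = h.snp_models(gm, subjects, "rA", covariates=())
        assert np.log(joint[0].terms["OR"].iloc[0]) == pytest.approx(
            np.log(mA.terms["OR"].iloc[0]), abs=0.1)

    def test_ld_partner_attenuates_in_joint_model(self):
        rng = np.random.default_rng(7)
        n = 6000
        causal = rng.binomial(2, 0.3, n)
        # strong-LD partner: copy with 10% per-allele noise
        noise = rng.binomial(1, 0.1, n)
        partner = np.clip(causal + noise - rng.binomial(1, 0.1, n), 0, 2)
        eta = -0.5 + 0.5 * causal
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_gm(np.column_stack([causal, partner]), rsids=["rC", "rP"])
        subjects = make_subjects(y)
        _, marg = h.snp_models(gm, subjects, "rP", covariates=())
        joint = h.joint_snp_model(gm, subjects, ["rC", "rP"], covariates=())
        assert abs(np.log(joint[1].terms["OR"].iloc[0])) < \
            abs(np.log(marg.terms["OR"].iloc[0]))

    def test_duplicate_snp_dropped(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, 500)
        gm = make_gm(np.column_stack([g, g]), rsids=["r1", "r2"])
        with pytest.warns(AliasingWarning):
            res = h.joint_snp_model(gm, make_subjects(rng.integers(0, 2, 500)),
                                    ["r1", "r2"], covariates=())
        assert sum(np.isnan(r.terms["OR"].iloc[0]) for r in res) == 1


class TestBhFdr:
    def test_six_pvalues_two_at_001(self):
        adj = h.bh_fdr([0.01, 0.01, 0.30, 0.35, 0.40, 0.45])
        assert adj[0] == pytest.approx(0.03) and adj[1] == pytest.approx(0.03)

    def test_eight_pvalues_min_002(self):
        adj = h.bh_fdr([0.02, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60])
        assert adj[0] == pytest.approx(0.16)

    def test_single_pvalue_unchanged(self):
        assert h.bh_fdr([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_properties_and_statsmodels_agreement(self, ps):
        adj = h.bh_fdr(ps)
        assert (adj <= 1.0).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()      # monotone step-up
        sm = pytest.importorskip("statsmodels.stats.multitest")
        ref = sm.multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)


class TestSensitivityAndInteraction:
    def test_independent_covariate_changes_little(self):
        rng = np.random.default_rng(10)
        n = 5000
        g = rng.binomial(2, 0.3, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.4 + 0.4 * g)))).astype(int)
        gm = make_gm(g.reshape(-1, 1), rsids=["rS"])
        subjects = make_subjects(y)
        res = h.confounder_sensitivity(gm, subjects, "rS", "smoking",
                                       covariates=("age", "sex"))
        assert res["pct_change"] < 5.0 and not res["flagged"]

    def test_strong_confounder_flagged(self):
        rng = np.random.default_rng(11)
        n = 5000
        conf = rng.binomial(1, 0.5, n)
        g = rng.binomial(2, np.where(conf == 1, 0.5, 0.15))
        eta = -1.0 + 1.5 * conf
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_gm(g.reshape(-1, 1), rsids=["rF"])
        subjects = make_subjects(y, hypertension=conf)
        res = h.confounder_sensitivity(gm, subjects, "rF", "hypertension",
                                       covariates=("age", "sex"))
        assert res["flagged"] and res["pct_change"] > 5.0

    def test_interaction_lrt_detects_planted_effect(self):
        rng = np.random.default_rng(12)
        n = 5000
        g = rng.binomial(2, 0.3, n)
        f = rng.binomial(1, 0.5, n)
        eta = -0.5 + 0.7 * g * f
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = make_gm(g.reshape(-1, 1), rsids=["rI"])
        subjects = make_subjects(y, hypertension=f)
        stat, df, p = h.snp_factor_interaction_lrt(
            gm, subjects, "rI", "hypertension", covariates=("age", "sex"))
        assert df == 1 and stat >= 0 and p < 0.05

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, 0.3, 100)
        gm = make_gm(g.reshape(-1, 1), rsids=["rL"])
        subjects = make_subjects(rng.integers(0, 2, 100),
                                 hypertension=np.zeros(100, int))
        with pytest.raises(ModelError):
            h.snp_factor_interaction_lrt(gm, subjects, "rL", "hypertension",
                                         covariates=("age",))


class TestSnpReport:
    def test_report_covers_all_snps_with_within_gene_fdr(self, study_cohort):
        _, gm, subjects, _ = study_cohort
        table = h.snp_report(gm, subjects)
        assert len(table) == gm.n_snps
        valid = table.dropna(subset=["trend_p"])
        assert (valid["fdr_trend_p"] >= valid["trend_p"] - 1e-12).all()
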