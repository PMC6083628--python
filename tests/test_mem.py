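"""Measurement-error model: closed forms, ML machinery, derived quantities."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dietval as dv
from dietval import _mvn, mem
from dietval.config import TOOL_INTERVIEWER, TOOL_ONLINE
from dietval.errors import (
    IdentifiabilityError,
    InputError,
    UndefinedResultError,
)
from dietval.mem import MEMParams, ToolMEM

from conftest import paired_dataset, protein_only_config


def make_params(beta1=1.0, s2T=1.0, s2r=0.0, s2eps=1.0):
    return MEMParams(
        mu_T=0.0,
        sigma2_T=s2T,
        sigma2_u=0.0,
        tools={TOOL_ONLINE: ToolMEM(0.0, beta1, s2r, s2eps)},
        tool_labels=(TOOL_ONLINE,),
        n_occasions=3,
    )


class TestClosedForms:
    def test_attenuation_is_the_classical_reliability_ratio(self):
        p = make_params(beta1=1.0, s2T=1.0, s2r=0.0, s2eps=1.0)
        assert dv.attenuation_factor(p, TOOL_ONLINE) == pytest.approx(0.5, rel=1e-12)
        assert dv.attenuation_factor(p, TOOL_ONLINE, k=math.inf) == pytest.approx(1.0, rel=1e-12)

    def test_attenuation_hand_oracle(self):
        p = make_params(beta1=0.6, s2T=0.25, s2r=0.05, s2eps=0.20)
        expected = 0.6 * 0.25 / (0.36 * 0.25 + 0.05 + 0.20)
        assert dv.attenuation_factor(p, TOOL_ONLINE) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4412, abs=5e-5)

    def test_correlation_oracles(self):
        perfect = make_params(beta1=1.0, s2T=1.0, s2r=0.0, s2eps=0.0)
        assert dv.correlation_with_truth(perfect, TOOL_ONLINE) == pytest.approx(1.0)
        p = make_params(beta1=1.0, s2T=1.0, s2r=0.0, s2eps=1.0)
        assert dv.correlation_with_truth(p, TOOL_ONLINE) == pytest.approx(1 / math.sqrt(2), rel=1e-12)
        q = make_params(beta1=0.6, s2T=0.25, s2r=0.05, s2eps=0.20)
        expected = 0.6 * 0.5 / math.sqrt(0.36 * 0.25 + 0.05 + 0.20)
        assert dv.correlation_with_truth(q, TOOL_ONLINE) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5145, abs=5e-5)

    def test_undefined_results_raise(self):
        degenerate = make_params(beta1=0.0, s2T=0.0, s2r=0.0, s2eps=0.0)
        with pytest.raises(UndefinedResultError):
            dv.attenuation_factor(degenerate, TOOL_ONLINE)
        with pytest.raises(UndefinedResultError):
            dv.correlation_with_truth(degenerate, TOOL_ONLINE)

    @given(
        beta1=st.floats(0.2, 1.5),
        s2T=st.floats(0.01, 0.5),
        s2r=st.floats(0.0, 0.1),
        s2eps=st.floats(1e-4, 0.5),
        k=st.integers(1, 7),
    )
    def test_rho_equals_lambda_times_sd_ratio(self, beta1, s2T, s2r, s2eps, k):
        """Model identity: rho = lambda * sd(Q_k) / sd(T)."""
        p = make_params(beta1, s2T, s2r, s2eps)
        lam = dv.attenuation_factor(p, TOOL_ONLINE, k=k)
        rho = dv.correlation_with_truth(p, TOOL_ONLINE, k=k)
        sd_q = math.sqrt(beta1 ** 2 * s2T + s2r + s2eps / k)
        assert rho == pytest.approx(lam * sd_q / math.sqrt(s2T), rel=1e-9)

    def test_attenuation_increasesing_in_k_to_closed_form_limit(self):
        p = make_params(beta1=0.62, s2T=0.09, s2r=0.02, s2eps=0.13)
        lams = [dv.attenuation_factor(p, TOOL_ONLINE, k=k) for k in (1, 2, 4, 7)]
        assert all(b > a for a, b in zip(lams, lams[1:]))
        limit = 0.62 * 0.09 / (0.62 ** 2 * 0.09 + 0.02)
        assert dv.attenuation_factor(p, TOOL_ONLINE, k=math.inf) == pytest.approx(limit, abs=1e-12)


class TestMeanPctDifference:
    def test_identical_values_give_zero(self):
        ds = paired_dataset([70.0, 80.0, 90.0], [70.0, 80.0, 90.0])
        assert dv.mean_pct_difference(ds, TOOL_ONLINE, "protein").value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("ratio,expected", [(1.1, 10.0), (0.5, -50.0)])
    def test_constant_ratio_oracle(self, ratio, expected):
        ref = [60.0, 75.0, 90.0, 120.0]
        ds = paired_dataset([ratio * v for v in ref], ref)
        res = dv.mean_pct_difference(ds, TOOL_ONLINE, "protein")
        assert res.value == pytest.approx(expected, rel=1e-9)
        assert res.ci_low <= res.value <= res.ci_high

    def test_no_overlap_raises(self):
        ds = paired_dataset([70.0], [70.0])
        ds.loc[ds.instrument == "biomarker", "protein"] = np.nan
        with pytest.raises(InputError):
            dv.mean_pct_difference(ds, TOOL_ONLINE, "protein")


class TestFit:
    def test_analytic_gradient_matches_central_differences(self):
        cfg = protein_only_config(120, seed=3, missingness=0.1)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        X, _, K = mem._wide_log_matrix(ds, "protein")
        groups = _mvn.pattern_groups(X)
        model = mem._mem_model(K, 2)
        theta = mem._pack(mem.moment_estimates(X, K), 1e-8) + 0.05
        _, g_ana = _mvn.nll_and_grad(theta, model, groups)
        for j in range(len(theta)):
            h = 1e-5 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            g_num = (
                _mvn.nll_and_grad(tp, model, groups)[0]
                - _mvn.nll_and_grad(tm, model, groups)[0]
            ) / (2 * h)
            assert g_num == pytest.approx(g_ana[j], rel=1e-4, abs=1e-4)

    def test_ml_equals_moment_oracle_on_complete_balanced_data(self):
        cfg = protein_only_config(500, seed=8, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein", compute_cov=False)
        X, _, K = mem._wide_log_matrix(ds, "protein")
        mom = dv.moment_estimates(X, K)
        assert fit.mu_T == pytest.approx(mom.mu_T, rel=1e-6)
        assert fit.sigma2_T == pytest.approx(mom.sigma2_T, rel=1e-6)
        assert fit.sigma2_u == pytest.approx(mom.sigma2_u, rel=1e-6)
        for tool in (TOOL_ONLINE, TOOL_INTERVIEWER):
            for attr in ("beta0", "beta1", "sigma2_r", "sigma2_eps"):
                assert getattr(fit.tools[tool], attr) == pytest.approx(
                    getattr(mom.tools[tool], attr), rel=1e-6, abs=1e-10
                )
        assert fit.sigma_rAB == pytest.approx(mom.sigma_rAB, rel=1e-6, abs=1e-10)

    def test_truth_recovery_on_large_complete_study(self):
        cfg = protein_only_config(5000, seed=17, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein")
        truth = cfg.nutrients["protein"]
        assert fit.sigma2_T == pytest.approx(truth.truth.sigma2_between, rel=0.15)
        assert fit.sigma2_u == pytest.approx(truth.truth.sigma2_within_ref, rel=0.15)
        tb = truth.tools[TOOL_ONLINE]
        est = fit.tools[TOOL_ONLINE]
        assert est.beta1 == pytest.approx(tb.beta1, abs=0.06)
        assert est.sigma2_eps == pytest.approx(tb.sigma2_within, rel=0.15)
        assert dv.attenuation_factor(fit, TOOL_ONLINE) == pytest.approx(0.30, abs=0.04)

    def test_near_perfect_instrument_yields_attenuation_one(self):
        cfg = protein_only_config(2000, seed=5, missingness=0.0)
        spec = cfg.nutrients["protein"]
        for tb in spec.tools.values():
            tb.beta0, tb.beta1 = 0.0, 1.0
            tb.sigma2_person, tb.sigma2_within = 0.0, 1e-6
        spec.rho_person_bias = 0.0
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein", compute_cov=False)
        assert dv.attenuation_factor(fit, TOOL_ONLINE) == pytest.approx(1.0, abs=0.01)

    def test_noiseless_data_hits_the_degenerate_closed_form(self):
        cfg = protein_only_config(60, seed=1, missingness=0.0)
        spec = cfg.nutrients["protein"]
        spec.truth.sigma2_within_ref = 0.0
        spec.rho_person_bias = 0.0
        for tb in spec.tools.values():
            tb.beta0, tb.beta1 = 0.0, 1.0
            tb.sigma2_person = tb.sigma2_within = 0.0
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein")
        assert fit.method == "moments"
        assert dv.attenuation_factor(fit, TOOL_ONLINE) == pytest.approx(1.0, abs=1e-9)
        assert dv.correlation_with_truth(fit, TOOL_ONLINE) == pytest.approx(1.0, abs=1e-9)

    def test_mar_robustness_of_attenuation(self):
        lam_full, lam_thin = [], []
        for s in range(6):
            cfg = protein_only_config(800, seed=300 + s, missingness=0.0)
            ds = dv.generate_validation_study(cfg, include_raw=False)
            lam_full.append(dv.attenuation_factor(dv.fit_mem(ds, "protein", compute_cov=False), TOOL_ONLINE))
            thin = dv.apply_mar_missingness(
                ds, {k: 0.2 for k in cfg.missingness}, seed=s
            )
            lam_thin.append(dv.attenuation_factor(dv.fit_mem(thin, "protein", compute_cov=False), TOOL_ONLINE))
        assert abs(np.mean(lam_full) - np.mean(lam_thin)) < 0.02

    def test_input_validation(self):
        cfg = protein_only_config(30, seed=0, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        bad = ds.copy()
        bad.loc[bad.index[0], "protein"] = -1.0
        with pytest.raises(InputError, match="non-positive"):
            dv.fit_mem(bad, "protein")
        single = ds[ds["occasion"] == 1]
        with pytest.raises(IdentifiabilityError):
            dv.fit_mem(single, "protein")
        no_ref = ds[ds["instrument"] != "biomarker"]
        with pytest.raises(IdentifiabilityError):
            dv.fit_mem(no_ref, "protein")


class TestDerivedCI:
    def test_zero_gradient_variance_gives_degenerate_interval(self):
        cfg = protein_only_config(200, seed=2, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein")
        fit.theta_cov = np.zeros_like(fit.theta_cov)
        lo, hi = dv.derived_ci(fit, "attenuation", TOOL_ONLINE)
        point = dv.attenuation_factor(fit, TOOL_ONLINE)
        assert lo == pytest.approx(point) and hi == pytest.approx(point)

    def test_delta_interval_brackets_the_estimate(self):
        cfg = protein_only_config(400, seed=12, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein")
        lo, hi = dv.derived_ci(fit, "attenuation", TOOL_ONLINE)
        assert lo < dv.attenuation_factor(fit, TOOL_ONLINE) < hi
        lo_r, hi_r = dv.derived_ci(fit, "correlation", TOOL_ONLINE)
        assert lo_r < dv.correlation_with_truth(fit, TOOL_ONLINE) < hi_r

    def test_bootstrap_is_seed_deterministic(self):
        cfg = protein_only_config(120, seed=6, missingness=0.0)
        ds = dv.generate_validation_study(cfg, include_raw=False)
        fit = dv.fit_mem(ds, "protein", compute_cov=False)
        kw = dict(
            method="bootstrap", dataset=ds, nutrient="protein", n_boot=30, seed=9
        )
        a = dv.derived_ci(fit, "attenuation", TOOL_ONLINE, **kw)
        b = dv.derived_ci(fit, "attenuation", TOOL_ONLINE, **kw)
        assert a == b
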