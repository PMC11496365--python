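import numpy as np
import pytest

from triageq import (UnsupportedConfigurationError, WorkflowConfig,
                     compute_waits, derive_rates, validate_config)
from triageq.models import select_model


def cfg_with(**kw):
    base = dict(f=0.0, prevalence_pi=0.1, se=0.95, sp=0.89, n_rad=1,
                read_time_interrupting=5.0, read_time_diseased=10.0,
                read_time_nondiseased=10.0, rho=0.8)
    base.update(kw)
    return WorkflowConfig(**base)


def erlang_c_wait(lam, mu, c):
    import math
    a = lam / mu
    rho = a / c
    num = a ** c / math.factorial(c) / (1 - rho)
    den = sum(a ** k / math.factorial(k) for k in range(c)) + num
    return (num / den) / (c * mu - lam)


class TestModelSelection:
    def test_equal_rates_selects_model1(self):
        assert select_model(cfg_with()) == 1

    def test_distinct_rates_selects_model2(self):
        assert select_model(cfg_with(read_time_nondiseased=15.0)) == 2

    def test_distinct_rates_with_two_radiologists_unsupported(self):
        with pytest.raises(UnsupportedConfigurationError):
            select_model(cfg_with(read_time_nondiseased=15.0, n_rad=2))


class TestClosedFormOracles:
    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.8])
    def test_without_cadt_matches_mm1(self, rho):
        cfg = cfg_with(rho=rho)
        without, _ = compute_waits(cfg)
        lam, mu = rho * 0.1, 0.1
        assert without.w_q_nonf == pytest.approx(lam / (mu * (mu - lam)),
                                                 rel=1e-6)

    @pytest.mark.parametrize("rho", [0.4, 0.8])
    def test_without_cadt_matches_erlang_c(self, rho):
        cfg = cfg_with(n_rad=2, rho=rho)
        without, _ = compute_waits(cfg)
        assert without.w_q_nonf == pytest.approx(
            erlang_c_wait(2 * rho * 0.1, 0.1, 2), rel=1e-6)

    def test_model2_matches_pollaczek_khinchine(self):
        # hyperexponential service: E[S] = 14.5 min, E[S^2] = 425 min^2
        cfg = cfg_with(read_time_nondiseased=15.0, rho=None,
                       lambda_total=0.05)
        without, _ = compute_waits(cfg)
        es, es2, lam = 14.5, 425.0, 0.05
        pk = lam * es2 / (2 * (1 - lam * es))
        assert pk == pytest.approx(38.6364, abs=1e-4)
        assert without.w_q_nonf == pytest.approx(pk, rel=1e-6)

    @pytest.mark.parametrize("se,sp", [(0.95, 0.89), (0.8, 0.7), (0.99, 0.5)])
    def test_with_cadt_matches_preemptive_priority_formulas(self, se, sp):
        """Two-class preemptive-resume formulas at one radiologist:
        W_+ = (1/mu)/(1-rho_+) - 1/mu; W_- = (1/mu)/((1-rho_+)(1-rho)) - 1/mu."""
        cfg = cfg_with(se=se, sp=sp)
        rates = derive_rates(validate_config(cfg))
        _, with_c = compute_waits(cfg)
        mu = 0.1
        rho_pos = rates.lambda_pos / mu
        rho_tot = rates.lambda_total / mu
        want_pos = 10.0 / (1 - rho_pos) - 10.0
        want_neg = 10.0 / ((1 - rho_pos) * (1 - rho_tot)) - 10.0
        assert with_c.w_q_pos == pytest.approx(want_pos, rel=1e-6)
        assert with_c.w_q_neg == pytest.approx(want_neg, rel=1e-6)

    def test_fig10_point_values(self, fig10_config):
        without, with_c = compute_waits(fig10_config)
        assert without.w_q_nonf == pytest.approx(40.0, rel=1e-6)
        assert with_c.w_q_pos == pytest.approx(1.83712, abs=1e-4)
        assert with_c.w_q_neg == pytest.approx(49.18561, abs=1e-4)


class TestDegenerateOperatingPoints:
    def test_all_negative_classifier_reproduces_without_cadt(self):
        cfg = cfg_with(se=0.0, sp=1.0)
        without, with_c = compute_waits(cfg)
        assert with_c.w_q_pos == 0.0          # empty class convention
        assert with_c.w_q_neg == pytest.approx(without.w_q_nonf, rel=1e-8)

    def test_all_positive_classifier_reproduces_without_cadt(self):
        cfg = cfg_with(se=1.0, sp=0.0)
        without, with_c = compute_waits(cfg)
        assert with_c.w_q_neg == 0.0
        assert with_c.w_q_pos == pytest.approx(without.w_q_nonf, rel=1e-8)


class TestInvariants:
    @pytest.mark.parametrize("rho", [0.5, 0.7, 0.9])
    @pytest.mark.parametrize("pi", [0.05, 0.1, 0.3])
    @pytest.mark.parametrize("se,sp", [(0.95, 0.89), (0.8, 0.8), (0.6, 0.95)])
    def test_work_conservation_grid(self, rho, pi, se, sp):
        """lambda_+ W_+ + lambda_- W_- = lambda_nonf W_nonf for Model 1
        at one radiologist with no interrupting images (27-point grid)."""
        cfg = cfg_with(rho=rho, prevalence_pi=pi, se=se, sp=sp)
        rates = derive_rates(validate_config(cfg))
        without, with_c = compute_waits(cfg)
        lhs = (rates.lambda_pos * with_c.w_q_pos
               + rates.lambda_neg * with_c.w_q_neg)
        rhs = rates.lambda_nonf * without.w_q_nonf
        assert lhs == pytest.approx(rhs, rel=1e-6)

    @pytest.mark.parametrize("kw", [
        dict(), dict(n_rad=2), dict(f=0.3), dict(read_time_nondiseased=15.0),
        dict(f=0.2, n_rad=2, rho=0.6),
    ])
    def test_priority_ordering(self, kw):
        cfg = cfg_with(**kw)
        without, with_c = compute_waits(cfg)
        assert with_c.w_q_pos <= without.w_q_nonf + 1e-9
        assert without.w_q_nonf <= with_c.w_q_neg + 1e-9

    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5])
    @pytest.mark.parametrize("rho", [0.5, 0.8])
    @pytest.mark.parametrize("read_nd", [10.0, 15.0])
    def test_model2_reduces_to_model1_grid(self, f, rho, read_nd):
        """With equal read rates the status-tracking chains reproduce the
        Model 1 waits; checked over a parameter grid (forced model=2 on an
        equal-rate config)."""
        cfg = cfg_with(f=f, rho=rho)
        wo1, wc1 = compute_waits(cfg, model=1)
        wo2, wc2 = compute_waits(cfg, model=2)
        assert wo2.w_q_nonf == pytest.approx(wo1.w_q_nonf, rel=1e-6)
        assert wc2.w_q_pos == pytest.approx(wc1.w_q_pos, rel=1e-6)
        assert wc2.w_q_neg == pytest.approx(wc1.w_q_neg, rel=1e-6)

    def test_model2_memory_phase_structure(self):
        """Truncated states are duplicated per interrupted-status copy and
        the in-service phase tracks the disease status."""
        from triageq.models import build_model2_without_cadt
        rates = derive_rates(validate_config(
            cfg_with(f=0.2, read_time_nondiseased=15.0, rho=0.7)))
        chain = build_model2_without_cadt(rates, 0.1)
        labels = chain.phase_labels
        assert any("serving D" in l for l in labels)
        assert any("serving ND" in l for l in labels)
        assert any("->D" in l for l in labels)
        assert any("->ND" in l for l in labels)
        # generator structure: the ->D copy returns only to 'serving D'
        rep_labels = [l for l in labels if "(0)" not in l and l != "empty"]
        i_d = rep_labels.index("serving D")
        i_nd = rep_labels.index("serving ND")
        for j, lab in enumerate(rep_labels):
            if "->D" in lab and "->ND" not in lab:
                assert chain.A1[j, i_nd] == 0.0
            if "->ND" in lab:
                assert chain.A1[j, i_d] == 0.0
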