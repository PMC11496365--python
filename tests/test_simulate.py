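import numpy as np
import pytest

from triageq import (SimConfig, WorkflowConfig, compute_waits, delta_metrics,
                     derive_rates, run_batch, simulate_run, validate_config)
from triageq.simulate import state_census_distribution


def cfg_with(**kw):
    base = dict(f=0.0, prevalence_pi=0.1, se=0.95, sp=0.89, n_rad=1,
                read_time_interrupting=5.0, read_time_diseased=10.0,
                read_time_nondiseased=10.0, rho=0.8)
    base.update(kw)
    return WorkflowConfig(**base)


class TestPairedWorlds:
    def test_no_reordering_when_nothing_is_positive(self):
        cfg = cfg_with(se=0.0, sp=1.0)
        recs = simulate_run(cfg, SimConfig(n_runs=1, patients_per_run=800,
                                           seed=5), 0)
        for r in recs:
            assert r.wait_without == r.wait_with

    def test_shared_arrivals_and_durations(self):
        cfg = cfg_with(f=0.2, rho=0.7)
        recs = simulate_run(cfg, SimConfig(n_runs=1, patients_per_run=500,
                                           seed=9), 0)
        # durations and arrivals are identical by construction; waits differ
        assert any(r.wait_without != r.wait_with for r in recs)
        assert all(r.wait_without >= 0 and r.wait_with >= 0 for r in recs)

    def test_reproducible_given_seed(self):
        cfg = cfg_with()
        sim = SimConfig(n_runs=2, patients_per_run=300, seed=21)
        a = run_batch(cfg, sim)
        b = run_batch(cfg, sim)
        assert a.delta_w_d == b.delta_w_d
        assert np.array_equal(a.per_run_delta_w_d, b.per_run_delta_w_d)

    def test_child_stream_isolation(self):
        # the first runs' means do not depend on how many runs follow
        cfg = cfg_with()
        r2 = run_batch(cfg, SimConfig(n_runs=2, patients_per_run=300, seed=4))
        r4 = run_batch(cfg, SimConfig(n_runs=4, patients_per_run=300, seed=4))
        assert np.allclose(r2.per_run_diseased_without,
                           r4.per_run_diseased_without[:2])


class TestClassFractions:
    def test_thinning_law(self):
        cfg = validate_config(cfg_with(f=0.3, se=0.8, sp=0.85))
        rates = derive_rates(cfg)
        recs = simulate_run(cfg, SimConfig(n_runs=1, patients_per_run=2000,
                                           seed=2), 0)
        n = len(recs)
        lam = rates.lambda_total
        for count, frac in (
                (sum(r.is_interrupting for r in recs), cfg.f),
                (sum(r.ai_positive for r in recs), rates.lambda_pos / lam),
                (sum((not r.is_interrupting) and (not r.ai_positive)
                     for r in recs), rates.lambda_neg / lam)):
            se3 = 3 * np.sqrt(frac * (1 - frac) / n)
            assert abs(count / n - frac) < se3


class TestStateCensus:
    def test_mm1_empty_probability(self):
        cfg = cfg_with(rho=0.6)
        recs = simulate_run(cfg, SimConfig(n_runs=1, patients_per_run=4000,
                                           seed=17), 0)
        dist = state_census_distribution(recs, "without")
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        p0 = sum(v for k, v in dist.items() if sum(k) == 0)
        # PASTA: pre-arrival snapshots estimate stationary probabilities
        assert p0 == pytest.approx(0.4, abs=0.05)

    def test_mean_count_matches_theory(self):
        cfg = cfg_with(rho=0.5)
        recs = simulate_run(cfg, SimConfig(n_runs=1, patients_per_run=6000,
                                           seed=19), 0)
        dist = state_census_distribution(recs, "without")
        mean_n = sum(sum(k) * v for k, v in dist.items())
        assert mean_n == pytest.approx(0.5 / 0.5, abs=0.12)   # L = rho/(1-rho)


class TestAgainstTheory:
    @pytest.mark.parametrize("kw", [
        dict(),                                        # Model 1, N=1
        dict(n_rad=2, rho=0.7),                        # Model 1, N=2
        dict(f=0.3, rho=0.7),                          # interrupting stream
        dict(read_time_nondiseased=15.0, rho=0.7),     # Model 2
    ])
    def test_theory_inside_simulation_ci(self, kw):
        cfg = cfg_with(**kw)
        res = run_batch(cfg, SimConfig(n_runs=40, patients_per_run=1000,
                                       seed=33))
        without, with_c = compute_waits(cfg)
        m = delta_metrics(without, with_c, cfg.se, cfg.sp)
        lo, hi = res.ci95_delta_w_d
        assert lo <= m.delta_w_d <= hi

    def test_interrupting_fraction_insensitivity(self):
        """Time savings with half the stream interrupting stay within the
        combined simulation uncertainty of the no-interruption savings."""
        sim = SimConfig(n_runs=60, patients_per_run=1000, seed=77)
        res0 = run_batch(cfg_with(), sim)
        res5 = run_batch(cfg_with(f=0.5), sim)

        def half_width(r):
            return 1.96 * r.per_run_delta_w_d.std(ddof=1) / np.sqrt(r.n_runs)

        gap = abs(res5.delta_w_d - res0.delta_w_d)
        assert gap < half_width(res0) + half_width(res5)

    def test_ci_width_scales_like_sqrt_runs(self):
        cfg = cfg_with(rho=0.6)

        def norm_width(n):
            r = run_batch(cfg, SimConfig(n_runs=n, patients_per_run=400,
                                         seed=55))
            lo, hi = r.ci95_normal_delta_w_d
            return hi - lo

        ratio = norm_width(40) / norm_width(80)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.25)
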