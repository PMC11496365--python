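import numpy as np
import pytest

from triageq import InstabilityError, WorkflowConfig, derive_rates, validate_config
from triageq.busy_periods import (busy_period_set_model1,
                                  busy_period_set_model2,
                                  mg1_busy_period_moments,
                                  mm1_busy_period_moments)
from triageq.phase_type import phase_type_moments


def rates_for(**kw):
    base = dict(f=0.2, prevalence_pi=0.1, se=0.95, sp=0.89, n_rad=2,
                read_time_interrupting=5.0, read_time_diseased=10.0,
                read_time_nondiseased=10.0, rho=0.7)
    base.update(kw)
    return derive_rates(validate_config(WorkflowConfig(**base)))


class TestMM1BusyPeriod:
    def test_closed_form_values(self):
        m = mm1_busy_period_moments(0.05, 0.2)
        assert m.as_tuple() == pytest.approx((6.66667, 118.519, 3950.62),
                                             rel=1e-5)

    def test_no_arrivals_reduces_to_exponential(self):
        m = mm1_busy_period_moments(0.0, 0.2)
        assert m.as_tuple() == pytest.approx((5.0, 50.0, 750.0), rel=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(InstabilityError):
            mm1_busy_period_moments(0.2, 0.2)

    def test_mg1_with_exponential_service_matches(self):
        lam, mu = 0.05, 0.2
        exp_mom = (1 / mu, 2 / mu ** 2, 6 / mu ** 3)
        got = mg1_busy_period_moments(lam, exp_mom)
        want = mm1_busy_period_moments(lam, mu)
        assert got.as_tuple() == pytest.approx(want.as_tuple(), rel=1e-12)


class TestModel1BusyPeriods:
    def test_conditional_probabilities_sum_per_start(self):
        specs = busy_period_set_model1(rates_for(), n_rad=2)
        by_start = {}
        for s in specs:
            by_start.setdefault(s.start_state, 0.0)
            by_start[s.start_state] += s.cond_prob
        assert set(by_start) == {"(2,0)", "(1,1)", "(0,2)"}
        for total in by_start.values():
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_all_fits_roundtrip(self):
        for s in busy_period_set_model1(rates_for(), n_rad=2):
            got = phase_type_moments(s.fitted)
            assert np.allclose(got.as_tuple(), s.moments.as_tuple(),
                               rtol=1e-8)

    def test_interrupting_free_limit(self):
        # with no interrupting arrivals, a busy period starting from two
        # AI-positive images can only end at (0,1); the (2,0) start keeps a
        # well-defined conditional law but receives no mass in the parent
        # chain (its trigger rate is lambda_f = 0)
        specs = busy_period_set_model1(rates_for(f=0.0), n_rad=2)
        b_02 = [s for s in specs if s.start_state == "(0,2)"]
        assert len(b_02) == 1
        assert b_02[0].end_state == "(0,1)"
        assert b_02[0].cond_prob == pytest.approx(1.0, abs=1e-10)

    def test_moments_match_monte_carlo(self, rng):
        """Conditional first-passage moments agree with a direct simulation
        of the two-class two-server sub-chain."""
        r = rates_for(rho=0.6)
        specs = {(s.start_state, s.end_state): s
                 for s in busy_period_set_model1(r, n_rad=2)}
        lam_f, mu_f = r.lambda_f, r.mu_f
        lam_p, mu_p = r.lambda_pos, r.mu_pos
        n_cycles = 20000
        samples = {k: [] for k in specs}
        for nf0, np0 in ((2, 0), (1, 1), (0, 2)):
            start = f"({nf0},{np0})"
            for _ in range(n_cycles // 3):
                nf, npos, t = nf0, np0, 0.0
                while nf + npos >= 2:
                    srv_f = min(nf, 2)
                    srv_p = min(npos, 2 - srv_f)
                    rates_vec = [lam_f, lam_p, srv_f * mu_f, srv_p * mu_p]
                    tot = sum(rates_vec)
                    t += rng.exponential(1.0 / tot)
                    u = rng.random() * tot
                    if u < rates_vec[0]:
                        nf += 1
                    elif u < rates_vec[0] + rates_vec[1]:
                        npos += 1
                    elif u < sum(rates_vec[:3]):
                        nf -= 1
                    else:
                        npos -= 1
                end = "(1,0)" if nf == 1 else "(0,1)"
                if (start, end) in samples:
                    samples[(start, end)].append(t)
        for key, times in samples.items():
            if len(times) < 200:
                continue
            times = np.asarray(times)
            m1 = specs[key].moments.m1
            se = times.std(ddof=1) / np.sqrt(times.size)
            assert abs(times.mean() - m1) < 3.5 * se, key


class TestModel2BusyPeriods:
    def test_symmetric_read_rates_give_identical_positive_starts(self):
        specs = dict((label_of(s), s) for _, __, s in
                     busy_period_set_model2(rates_for(n_rad=1)))
        assert specs["B2"].moments.as_tuple() == pytest.approx(
            specs["B3"].moments.as_tuple(), rel=1e-12)

    def test_no_positive_arrivals_reduces_to_mm1(self):
        r = rates_for(n_rad=1, se=0.0, sp=1.0)
        specs = busy_period_set_model2(r)
        assert len(specs) == 1
        _, rate, spec = specs[0]
        want = mm1_busy_period_moments(r.lambda_f, r.mu_f)
        assert spec.moments.as_tuple() == pytest.approx(want.as_tuple(),
                                                        rel=1e-12)

    def test_conditional_probabilities_are_one(self):
        for _, __, s in busy_period_set_model2(
                rates_for(n_rad=1, read_time_nondiseased=15.0)):
            assert s.cond_prob == 1.0

    def test_moments_match_monte_carlo(self, rng):
        """Busy-cycle simulation of the single-server high-priority chain
        (interrupting preempting AI-positive, disease-status memory)."""
        r = rates_for(n_rad=1, read_time_nondiseased=15.0, rho=0.6)
        specs = {s.label: s for _, __, s in busy_period_set_model2(r)}
        n_cycles = 20000
        for label, first in (("B1", "f"), ("B2", "D"), ("B3", "ND")):
            times = []
            for _ in range(n_cycles // 3):
                # remaining-work representation: busy period length depends
                # only on total work under work conservation
                work = rng.exponential(
                    {"f": 1 / r.mu_f, "D": 1 / r.mu_d, "ND": 1 / r.mu_nd}[first])
                t = 0.0
                lam_h = r.lambda_f + r.lambda_pos
                while work > 0:
                    gap = rng.exponential(1.0 / lam_h)
                    if gap >= work:
                        t += work
                        work = 0.0
                    else:
                        t += gap
                        work -= gap
                        if rng.random() < r.lambda_f / lam_h:
                            work += rng.exponential(1 / r.mu_f)
                        elif rng.random() < r.ppv:
                            work += rng.exponential(1 / r.mu_d)
                        else:
                            work += rng.exponential(1 / r.mu_nd)
                times.append(t)
            times = np.asarray(times)
            se = times.std(ddof=1) / np.sqrt(times.size)
            assert abs(times.mean() - specs[label].moments.m1) < 3.5 * se


def label_of(spec):
    return spec.label
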