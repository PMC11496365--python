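"""Busy-period probabilities, moments, and phase-type fits.

A busy period is a stretch of time during which every radiologist is
occupied by work of higher priority than the tagged class.  The truncated
workflow chains replace each busy period by a phase-type distribution
matched to its first three (conditional) moments.

Three computational routes are used:

* single high-priority class on one server — the classical M/M/1 busy
  period, closed form;
* several preemptively ordered high-priority classes on one server — the
  busy period depends only on the total workload, so it is the M/G/1 busy
  period of the pooled arrival stream with a mixture service law, optionally
  *initiated* by a specific first job (a "delay" busy period), again closed
  form;
* two high-priority classes on two servers — a genuinely two-dimensional
  first-passage problem, solved numerically on the truncated
  (interrupting, AI-positive) sub-chain for the conditional end-state
  probabilities and conditional moments of each of the six busy periods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import splu

from .config import DerivedRates
from .errors import InstabilityError
from .phase_type import ECParams, Moments, fit_ec

logger = logging.getLogger(__name__)

__all__ = [
    "BusyPeriodSpec",
    "mm1_busy_period_moments",
    "mg1_busy_period_moments",
    "busy_period_set_model1",
    "busy_period_set_model2",
]

_PROB_DROP = 1e-12


@dataclass(frozen=True)
class BusyPeriodSpec:
    """One busy period of a truncated chain.

    ``cond_prob`` is the probability that a busy period starting at
    ``start_state`` ends at ``end_state``; ``moments`` are the first three
    moments of the duration *conditioned* on that end state; ``fitted`` is
    the matched Erlang–Coxian distribution.  ``trigger`` names the explicit
    environment state and arrival class whose transition opens this busy
    period.
    """

    label: str
    start_state: str
    end_state: str
    cond_prob: float
    moments: Moments
    fitted: ECParams


def mm1_busy_period_moments(lam: float, mu: float) -> Moments:
    """First three moments of the M/M/1 busy period.

    ``m1 = 1/(mu(1-rho))``, ``m2 = 2/(mu^2 (1-rho)^3)``,
    ``m3 = 6 (1+rho)/(mu^3 (1-rho)^5)`` with ``rho = lam/mu``.  ``lam = 0``
    reduces to plain exponential-service moments ``k!/mu^k``.
    """
    if mu <= 0.0:
        raise InstabilityError("service rate must be positive")
    if lam >= mu:
        raise InstabilityError(
            f"busy period diverges: lambda={lam} >= mu={mu}")
    rho = lam / mu
    return Moments(
        1.0 / (mu * (1.0 - rho)),
        2.0 / (mu ** 2 * (1.0 - rho) ** 3),
        6.0 * (1.0 + rho) / (mu ** 3 * (1.0 - rho) ** 5),
    )


def mg1_busy_period_moments(lam: float,
                            service_moments: tuple[float, float, float],
                            initial_moments: Optional[tuple[float, float, float]]
                            = None) -> Moments:
    """Moments of an M/G/1 busy period, optionally initiated by a given job.

    For Poisson arrivals at rate ``lam`` with service moments
    ``(s1, s2, s3)`` and an initiating job with moments ``(g1, g2, g3)``
    (defaults to a regular arrival), the delay-busy-period moments are

    ``m1 = g1/(1-rho)``,
    ``m2 = g2/(1-rho)^2 + g1 lam s2/(1-rho)^3``,
    ``m3 = g3/(1-rho)^3 + 3 lam s2 g2/(1-rho)^4
          + g1 (lam s3/(1-rho)^4 + 3 lam^2 s2^2/(1-rho)^5)``,

    with ``rho = lam s1``.  Setting the initiator equal to the service law
    recovers the ordinary busy period; with exponential service it reduces
    to :func:`mm1_busy_period_moments`.
    """
    s1, s2, s3 = service_moments
    rho = lam * s1
    if rho >= 1.0:
        raise InstabilityError(f"busy period diverges: rho={rho} >= 1")
    g1, g2, g3 = initial_moments if initial_moments is not None else service_moments
    om = 1.0 - rho
    m1 = g1 / om
    m2 = g2 / om ** 2 + g1 * lam * s2 / om ** 3
    m3 = (g3 / om ** 3 + 3.0 * lam * s2 * g2 / om ** 4
          + g1 * (lam * s3 / om ** 4 + 3.0 * lam ** 2 * s2 ** 2 / om ** 5))
    return Moments(m1, m2, m3)


def _exp_moments(mu: float) -> tuple[float, float, float]:
    return (1.0 / mu, 2.0 / mu ** 2, 6.0 / mu ** 3)


def _mixture_moments(weights_rates: list[tuple[float, float]]
                     ) -> tuple[float, float, float]:
    """Raw moments of a hyperexponential mixture of exponentials."""
    out = [0.0, 0.0, 0.0]
    for w, mu in weights_rates:
        e = _exp_moments(mu)
        for k in range(3):
            out[k] += w * e[k]
    return tuple(out)  # type: ignore[return-value]


def aggregate_high_priority_busy(rates: DerivedRates, with_cadt: bool
                                 ) -> list[tuple[str, float, BusyPeriodSpec]]:
    """Busy periods above the tagged class for one radiologist (Model 1).

    Returns ``(trigger_class, trigger_rate, spec)`` tuples.  Without a CADt
    the only higher class is the interrupting stream; with a CADt the
    interrupting and AI-positive streams pool into a single workload, so the
    busy period opened by an arrival of either class is the M/G/1 delay busy
    period of the pooled stream initiated by that class's service time.
    """
    specs: list[tuple[str, float, BusyPeriodSpec]] = []
    if not with_cadt:
        if rates.lambda_f > 0.0:
            m = mm1_busy_period_moments(rates.lambda_f, rates.mu_f)
            specs.append(("interrupting", rates.lambda_f, BusyPeriodSpec(
                label="B_f", start_state="(1+, n)", end_state="(0, n)",
                cond_prob=1.0, moments=m, fitted=fit_ec(m))))
        return specs
    lam_h = rates.lambda_f + rates.lambda_pos
    if lam_h <= 0.0:
        return specs
    mix = []
    if rates.lambda_f > 0.0:
        mix.append((rates.lambda_f / lam_h, rates.mu_f))
    if rates.lambda_pos > 0.0:
        mix.append((rates.lambda_pos / lam_h, rates.mu_pos))
    s_mom = _mixture_moments(mix)
    for name, lam_i, mu_i in (("interrupting", rates.lambda_f, rates.mu_f),
                              ("ai_positive", rates.lambda_pos, rates.mu_pos)):
        if lam_i <= 0.0:
            continue
        m = mg1_busy_period_moments(lam_h, s_mom, _exp_moments(mu_i))
        specs.append((name, lam_i, BusyPeriodSpec(
            label=f"B_{name}", start_state=f"{name} arrival, server free",
            end_state="no high-priority work", cond_prob=1.0,
            moments=m, fitted=fit_ec(m))))
    return specs


# ---------------------------------------------------------------------------
# Model 1, two radiologists: six conditional busy periods from the
# two-dimensional (interrupting, AI-positive) sub-chain.
# ---------------------------------------------------------------------------

def _two_server_passage(lam_f: float, mu_f: float, lam_p: float, mu_p: float,
                        level_cap: int) -> dict:
    """First-passage analysis from total-2 states down to total-1 states.

    Transient states are ``(n_f, n_p)`` with ``n_f + n_p >= 2`` and
    ``n_f + n_p <= level_cap``; absorbing states are ``(1, 0)`` and
    ``(0, 1)``.  Interrupting work preempts AI-positive work, so with
    ``n_f`` interrupting images ``min(n_f, 2)`` servers read interrupting
    cases and the rest read AI-positive ones.  Returns absorption
    probabilities and conditional moments for the three start states.
    """
    idx: dict[tuple[int, int], int] = {}
    states: list[tuple[int, int]] = []
    for tot in range(2, level_cap + 1):
        for n_f in range(tot + 1):
            s = (n_f, tot - n_f)
            idx[s] = len(states)
            states.append(s)
    n = len(states)
    Q = lil_matrix((n, n))
    exit_10 = np.zeros(n)
    exit_01 = np.zeros(n)
    for s, i in idx.items():
        n_f, n_p = s
        tot = n_f + n_p
        out = 0.0
        srv_f = min(n_f, 2)
        srv_p = min(n_p, 2 - srv_f)
        rate_f_dep = srv_f * mu_f
        rate_p_dep = srv_p * mu_p
        # arrivals (dropped at the truncation cap: negligible mass there)
        if tot < level_cap:
            Q[i, idx[(n_f + 1, n_p)]] = lam_f
            Q[i, idx[(n_f, n_p + 1)]] = lam_p
            out += lam_f + lam_p
        if rate_f_dep > 0.0:
            t = (n_f - 1, n_p)
            if sum(t) >= 2:
                Q[i, idx[t]] = rate_f_dep
            elif t == (1, 0):
                exit_10[i] = rate_f_dep
            else:  # (0, 1)
                exit_01[i] = rate_f_dep
            out += rate_f_dep
        if rate_p_dep > 0.0:
            t = (n_f, n_p - 1)
            if sum(t) >= 2:
                Q[i, idx[t]] = rate_p_dep
            elif t == (1, 0):
                exit_10[i] = rate_p_dep
            else:
                exit_01[i] = rate_p_dep
            out += rate_p_dep
        Q[i, i] = -out
    lu = splu(Q.tocsc())

    starts = {"(2,0)": (2, 0), "(1,1)": (1, 1), "(0,2)": (0, 2)}
    # g0 = absorption probabilities, g_k = E[tau^k ; end] via Q g_k = -k g_{k-1}
    out: dict = {}
    for end_name, exit_vec in (("(1,0)", exit_10), ("(0,1)", exit_01)):
        g = -lu.solve(exit_vec)          # g0: Q g0 = -exit
        gk = g
        moments = [g]
        for k in (1, 2, 3):
            gk = -k * lu.solve(gk)
            moments.append(gk)
        for s_name, s in starts.items():
            i = idx[s]
            p = float(moments[0][i])
            entry = {"prob": p}
            if p > _PROB_DROP:
                entry["moments"] = tuple(float(moments[k][i]) / p
                                         for k in (1, 2, 3))
            out[(s_name, end_name)] = entry
    return out


def busy_period_set_model1(rates: DerivedRates, n_rad: int = 2,
                           level_cap: int = 200) -> list[BusyPeriodSpec]:
    """The six conditional busy periods of the two-radiologist with-CADt
    chain (B1..B6), fitted to phase type.

    Busy periods start when the second high-priority image (interrupting or
    AI-positive) enters the system and end when a single high-priority image
    remains.  The truncation cap of the passage sub-chain is doubled until
    the third moments are stable to ``1e-10`` relative.
    """
    if n_rad != 2:
        raise ValueError("the six-busy-period construction is specific to "
                         "two radiologists")
    util = (rates.lambda_f / rates.mu_f + rates.lambda_pos / rates.mu_pos) / 2.0
    if util >= 1.0 - 1e-9:
        raise InstabilityError(
            f"interrupting + AI-positive utilization {util:.4f} >= 1")
    cap = max(40, min(level_cap, 40))
    prev = None
    while True:
        res = _two_server_passage(rates.lambda_f, rates.mu_f,
                                  rates.lambda_pos, rates.mu_pos, cap)
        if prev is not None:
            worst = 0.0
            for key, entry in res.items():
                if "moments" not in entry or "moments" not in prev.get(key, {}):
                    continue
                for a, b in zip(entry["moments"], prev[key]["moments"]):
                    worst = max(worst, abs(a - b) / max(abs(b), 1e-300))
            if worst < 1e-10:
                break
        if cap >= level_cap:
            logger.warning("passage truncation cap %d reached", cap)
            break
        prev = res
        cap = min(cap * 2, level_cap)
    logger.debug("busy-period passage sub-chain truncated at total count %d", cap)

    naming = [
        ("B1", "(0,2)", "(0,1)"), ("B2", "(0,2)", "(1,0)"),
        ("B3", "(1,1)", "(0,1)"), ("B4", "(1,1)", "(1,0)"),
        ("B5", "(2,0)", "(0,1)"), ("B6", "(2,0)", "(1,0)"),
    ]
    specs = []
    for label, start, end in naming:
        entry = res[(start, end)]
        if entry["prob"] <= _PROB_DROP:
            continue
        m = Moments(*entry["moments"])
        specs.append(BusyPeriodSpec(label=label, start_state=start,
                                    end_state=end, cond_prob=entry["prob"],
                                    moments=m, fitted=fit_ec(m)))
    return specs


def busy_period_set_model2(rates: DerivedRates
                           ) -> list[tuple[str, float, BusyPeriodSpec]]:
    """Busy periods of the single-radiologist with-CADt chain when diseased
    and non-diseased read rates differ (B1..B3).

    All three end in the same state (no interrupting or AI-positive work
    left) so each conditional probability is 1; they differ by the job that
    opens them: an interrupting image (B1), or an AI-positive image whose
    service is diseased (B2) or non-diseased (B3).  Because the single
    server is work conserving, each is an M/G/1 delay busy period of the
    pooled interrupting + AI-positive stream.
    """
    lam_h = rates.lambda_f + rates.lambda_pos
    out: list[tuple[str, float, BusyPeriodSpec]] = []
    if lam_h <= 0.0:
        return out
    mix: list[tuple[float, float]] = []
    if rates.lambda_f > 0.0:
        mix.append((rates.lambda_f / lam_h, rates.mu_f))
    if rates.lambda_pos > 0.0:
        w = rates.lambda_pos / lam_h
        mix.append((w * rates.ppv, rates.mu_d))
        mix.append((w * (1.0 - rates.ppv), rates.mu_nd))
    s_mom = _mixture_moments(mix)
    triggers = [
        ("B1", "interrupting", rates.lambda_f, rates.mu_f,
         "(1+, 0+, n-)", "(0, 0, n-)"),
        ("B2", "ai_positive_diseased", rates.lambda_pos * rates.ppv,
         rates.mu_d, "(0+, 1+, D, n-)", "(0, 0, n-)"),
        ("B3", "ai_positive_nondiseased",
         rates.lambda_pos * (1.0 - rates.ppv), rates.mu_nd,
         "(0+, 1+, ND, n-)", "(0, 0, n-)"),
    ]
    for label, name, lam_i, mu_i, start, end in triggers:
        if lam_i <= _PROB_DROP * rates.lambda_total:
            continue
        m = mg1_busy_period_moments(lam_h, s_mom, _exp_moments(mu_i))
        out.append((name, lam_i, BusyPeriodSpec(
            label=label, start_state=start, end_state=end, cond_prob=1.0,
            moments=m, fitted=fit_ec(m))))
    return out
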