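"""Construction and solution of the truncated workflow Markov chains.

Two workflow models are covered, each in a without-CADt and a with-CADt
scenario:

* **Model 1** — diseased and non-diseased read rates equal, one or two
  radiologists.  States track per-class counts only; sojourns of the
  tagged class above the server capacity are replaced by phase-type busy
  periods (a single type per chain for one radiologist, the six
  conditional busy periods for two).
* **Model 2** — distinct diseased/non-diseased read rates, one
  radiologist.  The in-service phase additionally carries the disease
  status of the image being read, and truncated (busy) states are
  duplicated per the status of the interrupted image so the radiologist
  resumes the correct case.

Every chain is handed to the matrix-geometric solver and converted to a
mean queue wait via Little's law.  Interrupting-class waits are never
computed: under preemptive-resume priority they are unaffected by the
triage device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .busy_periods import (BusyPeriodSpec, aggregate_high_priority_busy,
                           busy_period_set_model1, busy_period_set_model2,
                           mm1_busy_period_moments)
from .config import DerivedRates, WorkflowConfig, derive_rates, validate_config
from .errors import InstabilityError, UnsupportedConfigurationError
from .phase_type import ECParams, fit_ec
from .qbd import QBDChain, solve_chain_wait

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioWaits",
    "build_model1_without_cadt",
    "build_model1_ai_positive",
    "build_model1_ai_negative",
    "build_model2_without_cadt",
    "build_model2_ai_positive",
    "build_model2_ai_negative",
    "compute_waits",
    "select_model",
]

_PROB_DROP = 1e-12


@dataclass(frozen=True)
class ScenarioWaits:
    """Mean queue waits (minutes) for one scenario of one model."""

    model: int
    scenario: Literal["without_cadt", "with_cadt"]
    w_q_nonf: Optional[float] = None
    w_q_pos: Optional[float] = None
    w_q_neg: Optional[float] = None


# ---------------------------------------------------------------------------
# generic builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _EnvState:
    name: str
    busy_servers: int


@dataclass(frozen=True)
class _Trigger:
    """High-priority arrival opening a busy period from an explicit state."""

    env_from: int
    rate: float
    branches: tuple[tuple[float, ECParams, int], ...]  # (prob, fit, env_end)


def _build_env_chain(lam_t: float, mu_t: float, n_rad: int,
                     env_states: Sequence[_EnvState],
                     env_trans: dict[tuple[int, int], float],
                     triggers: Sequence[_Trigger],
                     label: str) -> QBDChain:
    """QBD over (tagged count, environment phase) for Model 1 chains.

    Environment phases are the explicit high-priority states plus the
    phases of every busy-period branch; the tagged departure rate in an
    explicit state is ``min(level, free servers) * mu_t`` and zero inside a
    busy period.
    """
    phase_labels = [e.name for e in env_states]
    n_env = len(env_states)
    blocks: list[tuple[_Trigger, int, np.ndarray, np.ndarray, int]] = []
    offset = n_env
    for trig in triggers:
        for prob, fit, env_end in trig.branches:
            T, exit_rates = fit.subgenerator()
            k = T.shape[0]
            blocks.append((trig, offset, T, exit_rates, env_end))
            phase_labels.extend(
                f"busy[{trig.env_from}->{env_end}] phase {j}" for j in range(k))
            offset += k
    n_ph = offset

    loc = np.zeros((n_ph, n_ph))   # off-diagonal local transitions
    for (i, j), rate in env_trans.items():
        loc[i, j] += rate
    for trig in triggers:
        probs = [br[0] for br in trig.branches]
        total_p = sum(probs)
        for (t2, off, T, exit_rates, env_end), (prob, fit, _e) in zip(
                [b for b in blocks if b[0] is trig], trig.branches):
            entry = fit.entry_vector()
            loc[trig.env_from, off:off + T.shape[0]] += (
                trig.rate * prob / total_p * entry)
    for trig, off, T, exit_rates, env_end in blocks:
        k = T.shape[0]
        loc[off:off + k, off:off + k] += T - np.diag(np.diag(T))
        loc[off:off + k, env_end] += exit_rates
        # store total phase exit rate on the diagonal bookkeeping below
    hold = np.zeros(n_ph)          # total rate out through local transitions
    hold[:n_env] = 0.0
    for trig, off, T, exit_rates, env_end in blocks:
        k = T.shape[0]
        hold[off:off + k] = -np.diag(T)

    free = np.array([max(n_rad - e.busy_servers, 0) for e in env_states]
                    + [0] * (n_ph - n_env))

    def local_block(down_rates: np.ndarray) -> np.ndarray:
        out = loc.copy()
        rowsum = loc.sum(axis=1)
        # PH internal off-diagonals + exits are in loc; holding already counted
        np.fill_diagonal(out, -(rowsum + lam_t + down_rates))
        return out

    A0 = lam_t * np.eye(n_ph)
    down_full = free * mu_t
    A1 = local_block(down_full)
    A2 = np.diag(down_full.astype(float))

    boundary_local, boundary_up, boundary_down = [], [], []
    for lvl in range(n_rad):
        down = np.minimum(lvl, free) * mu_t
        boundary_local.append(local_block(down))
        boundary_up.append(A0.copy())
        boundary_down.append(np.diag(down.astype(float)) if lvl > 0 else None)
    return QBDChain(boundary_local=boundary_local, boundary_up=boundary_up,
                    boundary_down=boundary_down, A0=A0, A1=A1, A2=A2,
                    level_meaning=label, phase_labels=phase_labels,
                    class_rates=(lam_t, mu_t))


def _build_status_chain(lam_t: float, statuses: Sequence[tuple[str, float, float]],
                        busy: Sequence[tuple[str, float, ECParams]],
                        label: str) -> QBDChain:
    """QBD for single-radiologist chains whose in-service phase carries the
    disease status of the image being read (Model 2; Model 1 is the
    single-status special case).

    ``statuses`` lists ``(name, mix probability, service rate)`` of the
    tagged class; ``busy`` lists ``(name, trigger rate, fitted PH)`` of the
    busy periods opened by high-priority arrivals.  With several statuses
    each busy period is duplicated per the status of the interrupted image
    ("-> D" / "-> ND") plus a copy for busy periods that started with no
    tagged image in service; all copies share one set of fitted rates.
    """
    n_s = len(statuses)
    mix = np.array([s[1] for s in statuses])
    mu_s = np.array([s[2] for s in statuses])
    copies = list(range(n_s)) + [None] if n_s > 1 else [None]  # None = fresh

    # repeating-level phase layout: serving statuses, then busy blocks
    phase_labels = [f"serving {s[0]}" for s in statuses]
    rep_blocks = []   # (busy_idx, copy, offset, T, exit)
    off = n_s
    for b_idx, (b_name, rate, fit) in enumerate(busy):
        T, ex = fit.subgenerator()
        for c in copies:
            rep_blocks.append((b_idx, c, off, T, ex))
            tag = statuses[c][0] if c is not None else "fresh"
            phase_labels.extend(
                f"{b_name}->{tag} phase {j}" for j in range(T.shape[0]))
            off += T.shape[0]
    n_rep = off

    loc = np.zeros((n_rep, n_rep))
    for b_idx, c, off_b, T, ex in rep_blocks:
        k = T.shape[0]
        loc[off_b:off_b + k, off_b:off_b + k] += T - np.diag(np.diag(T))
        if c is not None:
            loc[off_b:off_b + k, c] += ex
        else:  # fresh: next tagged service drawn from the mix
            loc[off_b:off_b + k, :n_s] += np.outer(ex, mix)
    for b_idx, c, off_b, T, ex in rep_blocks:
        rate = busy[b_idx][1]
        if c is not None:              # busy opened while serving status c
            loc[c, off_b:off_b + T.shape[0]] += rate * busy[b_idx][2].entry_vector()
    hold = np.zeros(n_rep)
    for b_idx, c, off_b, T, ex in rep_blocks:
        hold[off_b:off_b + T.shape[0]] = -np.diag(T)

    down_rates = np.zeros(n_rep)
    down_rates[:n_s] = mu_s
    # fresh-copy busy periods can only be opened from the empty state, but the
    # chain may climb levels during them, so the phases exist at every level.
    fresh_rate_total = sum(rate for _, rate, _ in busy)

    A0 = lam_t * np.eye(n_rep)
    A2 = np.zeros((n_rep, n_rep))
    A2[:n_s, :n_s] = np.outer(mu_s, mix)
    A1 = loc.copy()
    np.fill_diagonal(A1, -(loc.sum(axis=1) + lam_t + down_rates))

    # boundary level 1: service completion empties the system
    dim0 = 1 + sum(T.shape[0] for b_idx, c, _, T, _ in rep_blocks if c is None)
    D1 = np.zeros((n_rep, dim0))
    D1[:n_s, 0] = mu_s

    # boundary level 0: empty state + fresh busy blocks
    zero_labels = ["empty"]
    zero_map = {}                   # rep offset -> level-0 offset (fresh blocks)
    off0 = 1
    for b_idx, c, off_b, T, ex in rep_blocks:
        if c is None:
            zero_map[off_b] = off0
            zero_labels.extend(
                f"(0) {busy[b_idx][0]} phase {j}" for j in range(T.shape[0]))
            off0 += T.shape[0]
    L0 = np.zeros((dim0, dim0))
    U0 = np.zeros((dim0, n_rep))
    for b_idx, c, off_b, T, ex in rep_blocks:
        if c is None:
            o0 = zero_map[off_b]
            k = T.shape[0]
            L0[o0:o0 + k, o0:o0 + k] += T - np.diag(np.diag(T))
            L0[o0:o0 + k, 0] += ex                   # busy ends -> empty
            L0[0, o0:o0 + k] += busy[b_idx][1] * busy[b_idx][2].entry_vector()
            U0[o0:o0 + k, off_b:off_b + k] = lam_t * np.eye(k)
    U0[0, :n_s] = lam_t * mix
    np.fill_diagonal(L0, np.diag(L0) - (L0 - np.diag(np.diag(L0))).sum(axis=1)
                     - U0.sum(axis=1))

    mean_service = float(mix @ (1.0 / mu_s))
    return QBDChain(
        boundary_local=[L0, A1.copy()], boundary_up=[U0, A0.copy()],
        boundary_down=[None, D1], A0=A0, A1=A1, A2=A2,
        level_meaning=label, phase_labels=zero_labels + phase_labels,
        class_rates=(lam_t, 1.0 / mean_service))


# ---------------------------------------------------------------------------
# Model 1 chains
# ---------------------------------------------------------------------------

def _model1_two_class_chain(lam_high: float, mu_high: float,
                            lam_t: float, mu_t: float, n_rad: int,
                            label: str) -> QBDChain:
    """Tagged class under a single higher-priority class on 1 or 2 servers.

    The busy period during which all radiologists handle high-priority work
    is the M/M/1 busy period with service rate ``n_rad * mu_high``, fitted
    to phase type (two-phase Coxian; its relative variance always allows it).
    """
    if n_rad not in (1, 2):
        raise UnsupportedConfigurationError(
            "analytic Model 1 chains cover one or two radiologists; use the "
            "simulator for more")
    env = [_EnvState("n_h=0", 0)]
    env_trans: dict[tuple[int, int], float] = {}
    triggers = []
    if lam_high > 0.0:
        if n_rad == 1:
            fit = fit_ec(mm1_busy_period_moments(lam_high, mu_high))
            triggers.append(_Trigger(0, lam_high, ((1.0, fit, 0),)))
        else:
            env.append(_EnvState("n_h=1", 1))
            env_trans = {(0, 1): lam_high, (1, 0): mu_high}
            fit = fit_ec(mm1_busy_period_moments(lam_high, 2.0 * mu_high))
            triggers.append(_Trigger(1, lam_high, ((1.0, fit, 1),)))
    return _build_env_chain(lam_t, mu_t, n_rad, env, env_trans, triggers, label)


def build_model1_without_cadt(rates: DerivedRates, n_rad: int) -> QBDChain:
    """Without-CADt chain over (interrupting, non-interrupting) counts."""
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_nonf / rates.mu_nonf, n_rad,
                       "interrupting + non-interrupting")
    return _model1_two_class_chain(rates.lambda_f, rates.mu_f,
                                   rates.lambda_nonf, rates.mu_nonf, n_rad,
                                   "non-interrupting images in system")


def build_model1_ai_positive(rates: DerivedRates, n_rad: int) -> QBDChain:
    """AI-positive chain: the without-CADt chain with the AI-positive class
    substituted for the non-interrupting one (the AI-negative class is
    invisible to it under preemptive-resume priority)."""
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_pos / rates.mu_pos, n_rad,
                       "interrupting + AI-positive")
    return _model1_two_class_chain(rates.lambda_f, rates.mu_f,
                                   rates.lambda_pos, rates.mu_pos, n_rad,
                                   "AI-positive images in system")


def build_model1_ai_negative(rates: DerivedRates,
                             busy: Optional[list[BusyPeriodSpec]] = None,
                             n_rad: int = 1) -> QBDChain:
    """AI-negative chain under the interrupting + AI-positive environment.

    For one radiologist the high-priority classes pool into aggregated
    busy periods; for two radiologists the explicit states
    ``(0,0), (1,0), (0,1)`` are kept and the six conditional busy periods
    (B1..B6) route arrivals beyond capacity back to the correct end state
    with their conditional probabilities.
    """
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_pos / rates.mu_pos
                       + rates.lambda_neg / rates.mu_neg, n_rad, "all classes")
    lam_t, mu_t = rates.lambda_neg, rates.mu_neg
    label = "AI-negative images in system"
    if n_rad == 1:
        env = [_EnvState("idle-of-high", 0)]
        triggers = []
        for name, rate, spec in aggregate_high_priority_busy(rates, True):
            triggers.append(_Trigger(0, rate, ((1.0, spec.fitted, 0),)))
        return _build_env_chain(lam_t, mu_t, 1, env, {}, triggers, label)
    if n_rad != 2:
        raise UnsupportedConfigurationError(
            "analytic Model 1 chains cover one or two radiologists")
    if busy is None:
        busy = busy_period_set_model1(rates, n_rad=2)
    spec_by_key = {(s.start_state, s.end_state): s for s in busy}
    # explicit states, pruning classes with no arrivals
    env = [_EnvState("(0,0)", 0)]
    env_idx: dict[str, int] = {}
    env_trans: dict[tuple[int, int], float] = {}
    if rates.lambda_f > 0.0:
        env_idx["(1,0)"] = len(env)
        env.append(_EnvState("(1,0)", 1))
        env_trans[(0, env_idx["(1,0)"])] = rates.lambda_f
        env_trans[(env_idx["(1,0)"], 0)] = rates.mu_f
    if rates.lambda_pos > 0.0:
        env_idx["(0,1)"] = len(env)
        env.append(_EnvState("(0,1)", 1))
        env_trans[(0, env_idx["(0,1)"])] = rates.lambda_pos
        env_trans[(env_idx["(0,1)"], 0)] = rates.mu_pos
    triggers = []
    for from_name, arr_rate, start in (
            ("(1,0)", rates.lambda_f, "(2,0)"),
            ("(1,0)", rates.lambda_pos, "(1,1)"),
            ("(0,1)", rates.lambda_f, "(1,1)"),
            ("(0,1)", rates.lambda_pos, "(0,2)")):
        if arr_rate <= 0.0 or from_name not in env_idx:
            continue
        branches = []
        for end in ("(1,0)", "(0,1)"):
            spec = spec_by_key.get((start, end))
            if (spec is not None and spec.cond_prob > _PROB_DROP
                    and end in env_idx):
                branches.append((spec.cond_prob, spec.fitted, env_idx[end]))
        if branches:
            triggers.append(_Trigger(env_idx[from_name], arr_rate,
                                     tuple(branches)))
    return _build_env_chain(lam_t, mu_t, 2, env, env_trans, triggers, label)


# ---------------------------------------------------------------------------
# Model 2 chains (one radiologist, distinct read rates)
# ---------------------------------------------------------------------------

def _statuses(mix_d: float, mu_d: float, mu_nd: float
              ) -> list[tuple[str, float, float]]:
    if mix_d >= 1.0 - _PROB_DROP:
        return [("D", 1.0, mu_d)]
    if mix_d <= _PROB_DROP:
        return [("ND", 1.0, mu_nd)]
    return [("D", mix_d, mu_d), ("ND", 1.0 - mix_d, mu_nd)]


def build_model2_without_cadt(rates: DerivedRates, pi: float) -> QBDChain:
    """Without-CADt chain tracking the disease status of the image in
    service; truncated interrupting busy periods are duplicated per the
    status to resume, sharing a single set of fitted rates."""
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_nonf / rates.mu_nonf, 1,
                       "interrupting + non-interrupting")
    busy = []
    if rates.lambda_f > 0.0:
        fit = fit_ec(mm1_busy_period_moments(rates.lambda_f, rates.mu_f))
        busy.append(("interrupting", rates.lambda_f, fit))
    return _build_status_chain(
        rates.lambda_nonf, _statuses(pi, rates.mu_d, rates.mu_nd), busy,
        "non-interrupting images in system")


def build_model2_ai_positive(rates: DerivedRates) -> QBDChain:
    """AI-positive chain: the Model 2 without-CADt chain with the
    substitution lambda -> lambda_+, service mix by PPV."""
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_pos / rates.mu_pos, 1,
                       "interrupting + AI-positive")
    busy = []
    if rates.lambda_f > 0.0:
        fit = fit_ec(mm1_busy_period_moments(rates.lambda_f, rates.mu_f))
        busy.append(("interrupting", rates.lambda_f, fit))
    return _build_status_chain(
        rates.lambda_pos, _statuses(rates.ppv, rates.mu_d, rates.mu_nd), busy,
        "AI-positive images in system")


def build_model2_ai_negative(rates: DerivedRates,
                             busy: Optional[list] = None) -> QBDChain:
    """AI-negative chain whose phases carry the disease status of the
    AI-negative image in service (mix 1 - NPV) and route each busy period
    (B1..B3) back to the matching interrupted status."""
    _check_utilization(rates.lambda_f / rates.mu_f
                       + rates.lambda_pos / rates.mu_pos
                       + rates.lambda_neg / rates.mu_neg, 1, "all classes")
    if busy is None:
        busy = busy_period_set_model2(rates)
    busy_args = [(name, rate, spec.fitted) for name, rate, spec in busy]
    return _build_status_chain(
        rates.lambda_neg,
        _statuses(1.0 - rates.npv, rates.mu_d, rates.mu_nd), busy_args,
        "AI-negative images in system")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _check_utilization(load: float, n_rad: int, what: str) -> None:
    util = load / n_rad
    if util >= 1.0 - 1e-9:
        raise InstabilityError(
            f"{what} utilization {util:.4f} is at or above capacity")


def select_model(cfg: WorkflowConfig) -> int:
    """Model 1 when diseased and non-diseased read rates are equal, else
    Model 2 (which requires a single radiologist)."""
    if cfg.equal_read_rates:
        return 1
    if cfg.n_rad != 1:
        raise UnsupportedConfigurationError(
            "distinct diseased/non-diseased read times are only supported "
            "with one radiologist (Model 2)")
    return 2


def compute_waits(cfg: WorkflowConfig,
                  model: Optional[int] = None) -> tuple[ScenarioWaits, ScenarioWaits]:
    """End-to-end pipeline: rates -> busy periods -> chains -> waits.

    Returns the without-CADt and with-CADt scenario waits.  Classes with no
    arrivals (e.g. AI-positive at Se = 0, Sp = 1) have zero wait by
    convention; their weight in the diseased/non-diseased mixtures is zero.
    """
    cfg = validate_config(cfg)
    model = select_model(cfg) if model is None else model
    rates = derive_rates(cfg)

    if model == 1:
        chain_no = build_model1_without_cadt(rates, cfg.n_rad)
        chain_pos = build_model1_ai_positive(rates, cfg.n_rad)
        chain_neg = build_model1_ai_negative(rates, n_rad=cfg.n_rad)
    elif model == 2:
        if cfg.n_rad != 1:
            raise UnsupportedConfigurationError(
                "Model 2 requires exactly one radiologist")
        chain_no = build_model2_without_cadt(rates, cfg.prevalence_pi)
        chain_pos = build_model2_ai_positive(rates)
        chain_neg = build_model2_ai_negative(rates)
    else:
        raise ValueError(f"unknown model {model!r}")

    w_nonf = solve_chain_wait(chain_no).w_queue
    w_pos = solve_chain_wait(chain_pos).w_queue
    w_neg = solve_chain_wait(chain_neg).w_queue
    logger.info("model %d waits (min): W_q_nonf=%.4f W_q_+=%.4f W_q_-=%.4f",
                model, w_nonf, w_pos, w_neg)
    without = ScenarioWaits(model=model, scenario="without_cadt",
                            w_q_nonf=w_nonf)
    with_c = ScenarioWaits(model=model, scenario="with_cadt",
                           w_q_pos=w_pos, w_q_neg=w_neg)
    return without, with_c
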