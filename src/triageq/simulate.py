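"""Paired two-world discrete-event simulation of the reading queue.

Every simulated patient image is placed simultaneously into two worlds that
share the identical arrival stream and read durations: one where the queue
is ordered only by interrupting status (without CADt) and one where
AI-positive images form a middle priority class (with CADt).  Both worlds
run preemptive-resume priority with FIFO order inside each class, so the
per-image wait difference isolates the effect of the triage device.

Randomness is drawn from one root seed with per-run child streams, in a
fixed order per patient: interarrival time, interrupting flag, disease
flag, AI-call flag, read duration.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import WorkflowConfig, derive_rates, validate_config

__all__ = [
    "SimConfig",
    "PatientRecord",
    "SimResult",
    "simulate_run",
    "run_batch",
    "state_census_distribution",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol: independent runs of ~2000 patients each."""

    n_runs: int = 200
    patients_per_run: int = 2000
    seed: int = 0
    burn_in: int = 0          # discarded leading images per run

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.patients_per_run < 1:
            raise ValueError("n_runs and patients_per_run must be positive")
        if not 0 <= self.burn_in < self.patients_per_run:
            raise ValueError("burn_in must be smaller than patients_per_run")


@dataclass
class PatientRecord:
    """One simulated image, tracked through both worlds."""

    arrival_time: float
    is_interrupting: bool
    is_diseased: bool
    ai_positive: bool
    read_duration: float
    wait_without: float = np.nan
    wait_with: float = np.nan
    state_census_without: tuple[int, ...] = ()
    state_census_with: tuple[int, ...] = ()


@dataclass(frozen=True)
class SimResult:
    """Aggregated paired-simulation output.

    ``ci95_*`` intervals are the 2.5/97.5 percentiles of the per-run mean
    diseased wait difference; ``ci95_normal_*`` is the normal-theory
    interval of the grand mean over runs.  Waits are in minutes and are
    queue waits (response minus read duration).
    """

    mean_wait: dict
    mean_diseased_wait_without: float
    mean_diseased_wait_with: float
    delta_w_d: float
    delta_w_nd: float
    ci95_delta_w_d: tuple[float, float]
    ci95_normal_delta_w_d: tuple[float, float]
    per_run_delta_w_d: np.ndarray
    per_run_diseased_without: np.ndarray
    per_run_diseased_with: np.ndarray
    n_runs: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mean_wait_min": self.mean_wait,
            "mean_diseased_wait_without_min": self.mean_diseased_wait_without,
            "mean_diseased_wait_with_min": self.mean_diseased_wait_with,
            "delta_w_d_min": self.delta_w_d,
            "delta_w_nd_min": self.delta_w_nd,
            "ci95_delta_w_d_min": list(self.ci95_delta_w_d),
            "ci95_normal_delta_w_d_min": list(self.ci95_normal_delta_w_d),
            "n_runs": self.n_runs,
            "seed": self.seed,
        }


class _World:
    """Preemptive-resume multi-server priority queue over shared jobs.

    ``priorities``: per-job class index (0 = highest).  Within a class, jobs
    are served in arrival order; a preempted job resumes before later
    arrivals of its class.  When a higher-priority image arrives and all
    servers are busy, the server working on the lowest-priority,
    most-recently-started job is preempted.
    """

    def __init__(self, n_classes: int, n_servers: int):
        self.n_classes = n_classes
        self.n_servers = n_servers
        self.queues: list[list[int]] = [[] for _ in range(n_classes)]
        # serving: job -> [completion_time, start_of_quantum]
        self.serving: dict[int, list[float]] = {}
        self.remaining: dict[int, float] = {}
        self.prio: dict[int, int] = {}
        self.in_system: list[int] = [0] * n_classes
        self.depart_time: dict[int, float] = {}

    def next_completion(self) -> tuple[float, int]:
        if not self.serving:
            return (np.inf, -1)
        job = min(self.serving, key=lambda j: self.serving[j][0])
        return (self.serving[job][0], job)

    def _start(self, job: int, now: float) -> None:
        self.serving[job] = [now + self.remaining[job], now]
        del self.remaining[job]

    def _preempt(self, job: int, now: float) -> None:
        comp, _ = self.serving.pop(job)
        self.remaining[job] = comp - now
        insort(self.queues[self.prio[job]], job)   # job ids follow arrival order

    def _schedule(self, now: float) -> None:
        # fill idle servers with the best waiting jobs
        while len(self.serving) < self.n_servers:
            for q in self.queues:
                if q:
                    self._start(q.pop(0), now)
                    break
            else:
                return

    def arrive(self, job: int, prio: int, duration: float, now: float) -> None:
        self.prio[job] = prio
        self.remaining[job] = duration
        self.in_system[prio] += 1
        self.queues[prio].append(job)
        if len(self.serving) >= self.n_servers:
            # preempt the worst served job if strictly lower priority
            worst = max(self.serving,
                        key=lambda j: (self.prio[j], self.serving[j][1]))
            if self.prio[worst] > prio:
                self._preempt(worst, now)
        self._schedule(now)

    def complete(self, job: int, now: float) -> None:
        del self.serving[job]
        self.in_system[self.prio[job]] -= 1
        self.depart_time[job] = now
        self._schedule(now)


def _gen_patients(cfg: WorkflowConfig, n: int, rng: np.random.Generator
                  ) -> list[PatientRecord]:
    rates = derive_rates(cfg)
    lam = rates.lambda_total
    arr = np.cumsum(rng.exponential(1.0 / lam, size=n))
    u_int = rng.random(n) < cfg.f
    u_dis = rng.random(n) < cfg.prevalence_pi
    u_ai = rng.random(n)
    base = rng.exponential(1.0, size=n)
    recs = []
    for i in range(n):
        interrupting = bool(u_int[i])
        diseased = (not interrupting) and bool(u_dis[i])
        if interrupting:
            ai_pos = False
            dur = base[i] / rates.mu_f
        elif diseased:
            ai_pos = bool(u_ai[i] < cfg.se)
            dur = base[i] / rates.mu_d
        else:
            ai_pos = bool(u_ai[i] < 1.0 - cfg.sp)
            dur = base[i] / rates.mu_nd
        recs.append(PatientRecord(arrival_time=float(arr[i]),
                                  is_interrupting=interrupting,
                                  is_diseased=diseased, ai_positive=ai_pos,
                                  read_duration=float(dur)))
    return recs


def _run_world(records: Sequence[PatientRecord], n_servers: int,
               with_cadt: bool) -> None:
    """Evolve one world to completion, filling waits and censuses in place."""
    if with_cadt:
        prio_of = [0 if r.is_interrupting else (1 if r.ai_positive else 2)
                   for r in records]
        n_classes = 3
    else:
        prio_of = [0 if r.is_interrupting else 1 for r in records]
        n_classes = 2
    world = _World(n_classes, n_servers)
    i = 0
    n = len(records)
    while i < n or world.serving:
        t_arr = records[i].arrival_time if i < n else np.inf
        t_comp, job = world.next_completion()
        if t_arr <= t_comp:
            census = tuple(world.in_system)
            if with_cadt:
                records[i].state_census_with = census
            else:
                records[i].state_census_without = census
            world.arrive(i, prio_of[i], records[i].read_duration, t_arr)
            i += 1
        else:
            world.complete(job, t_comp)
    for j, r in enumerate(records):
        wait = world.depart_time[j] - r.arrival_time - r.read_duration
        wait = max(wait, 0.0)
        if with_cadt:
            r.wait_with = wait
        else:
            r.wait_without = wait


def simulate_run(cfg: WorkflowConfig, sim: SimConfig,
                 run_index: int = 0) -> list[PatientRecord]:
    """One paired simulation run; both worlds share arrivals and durations."""
    cfg = validate_config(cfg)
    root = np.random.SeedSequence(sim.seed)
    child = root.spawn(sim.n_runs)[run_index] if run_index < sim.n_runs \
        else np.random.SeedSequence(entropy=sim.seed, spawn_key=(run_index,))
    rng = np.random.default_rng(child)
    records = _gen_patients(cfg, sim.patients_per_run, rng)
    _run_world(records, cfg.n_rad, with_cadt=False)
    _run_world(records, cfg.n_rad, with_cadt=True)
    return records[sim.burn_in:]


def run_batch(cfg: WorkflowConfig, sim: SimConfig) -> SimResult:
    """Full protocol: ``n_runs`` paired runs, aggregated with 95% CIs."""
    cfg = validate_config(cfg)
    per_run_d_wo, per_run_d_wi, per_run_nd_wo, per_run_nd_wi = [], [], [], []
    sums: dict[str, list[float]] = {k: [0.0, 0.0] for k in
                                    ("interrupting", "ai_positive",
                                     "ai_negative", "non_interrupting")}
    for run in range(sim.n_runs):
        recs = simulate_run(cfg, sim, run)
        d_wo = [r.wait_without for r in recs if r.is_diseased]
        d_wi = [r.wait_with for r in recs if r.is_diseased]
        nd_wo = [r.wait_without for r in recs
                 if not r.is_diseased and not r.is_interrupting]
        nd_wi = [r.wait_with for r in recs
                 if not r.is_diseased and not r.is_interrupting]
        if d_wo:
            per_run_d_wo.append(float(np.mean(d_wo)))
            per_run_d_wi.append(float(np.mean(d_wi)))
        if nd_wo:
            per_run_nd_wo.append(float(np.mean(nd_wo)))
            per_run_nd_wi.append(float(np.mean(nd_wi)))
        for r in recs:
            if r.is_interrupting:
                key = "interrupting"
            else:
                sums["non_interrupting"][0] += r.wait_without
                sums["non_interrupting"][1] += 1
                key = "ai_positive" if r.ai_positive else "ai_negative"
            sums[key][0] += r.wait_with if key != "interrupting" else r.wait_without
            sums[key][1] += 1

    d_wo_arr = np.asarray(per_run_d_wo)
    d_wi_arr = np.asarray(per_run_d_wi)
    delta_runs = d_wi_arr - d_wo_arr
    delta_nd = (float(np.mean(per_run_nd_wi)) - float(np.mean(per_run_nd_wo))
                if per_run_nd_wo else 0.0)
    mean_delta = float(np.mean(delta_runs))
    lo, hi = (np.percentile(delta_runs, [2.5, 97.5])
              if delta_runs.size > 1 else (mean_delta, mean_delta))
    se = (float(np.std(delta_runs, ddof=1)) / np.sqrt(delta_runs.size)
          if delta_runs.size > 1 else 0.0)
    mean_wait = {k: (s / c if c else 0.0) for k, (s, c) in sums.items()}
    return SimResult(
        mean_wait=mean_wait,
        mean_diseased_wait_without=float(np.mean(d_wo_arr)),
        mean_diseased_wait_with=float(np.mean(d_wi_arr)),
        delta_w_d=mean_delta,
        delta_w_nd=delta_nd,
        ci95_delta_w_d=(float(lo), float(hi)),
        ci95_normal_delta_w_d=(mean_delta - 1.96 * se, mean_delta + 1.96 * se),
        per_run_delta_w_d=delta_runs,
        per_run_diseased_without=d_wo_arr,
        per_run_diseased_with=d_wi_arr,
        n_runs=sim.n_runs,
        seed=sim.seed,
    )


def state_census_distribution(records: Sequence[PatientRecord],
                              world: str = "without") -> dict[tuple[int, ...], float]:
    """Empirical distribution of pre-arrival per-class counts.

    By PASTA (Poisson arrivals see time averages) this estimates the
    stationary state probabilities of the corresponding chain.
    """
    attr = "state_census_without" if world == "without" else "state_census_with"
    counts: dict[tuple[int, ...], int] = {}
    n = 0
    for r in records:
        c = getattr(r, attr)
        if c == ():
            continue
        counts[c] = counts.get(c, 0) + 1
        n += 1
    return {k: v / n for k, v in counts.items()}
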