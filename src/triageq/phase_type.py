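"""Three-moment phase-type (Erlang–Coxian) fitting of busy periods.

The matrix-geometric workflow models replace every busy period — an interval
during which all radiologists are occupied by higher-priority work — with a
small phase-type distribution matched to the busy period's first three raw
moments.  The family used here is the Erlang–Coxian (EC) shape: an optional
run of Erlang phases with a common rate feeding a two-phase Coxian.

For the squared coefficient of variation ``c2 >= 1/2`` a two-phase Coxian
alone can match three moments and the fit is closed form: with
``h2 = m2/2`` and ``h3 = m3/6``, the first-phase mean ``A = 1/lambda_x1``
solves the quadratic

    (h2 - m1^2) A^2 + (m1 h2 - h3) A + (m1 h3 - h2^2) = 0,

after which ``B = (A m1 - h2)/(A - m1)`` and ``p_x = (m1 - A)/B``.  Moment
triples with lower relative variance need Erlang phases in front; those fits
are found by solving the exact three-equation system numerically inside the
EC family and are always verified by round-tripping through the closed-form
moment oracle :func:`phase_type_moments`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .errors import InfeasibleMomentsError

__all__ = [
    "Moments",
    "ECParams",
    "needs_erlang_stage",
    "fit_coxian2",
    "fit_ec",
    "phase_type_moments",
    "sample_phase_type",
]

_PROB_TOL = 1e-12
_FIT_RTOL = 1e-8


def _expit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-min(z, 700.0)))
    e = math.exp(max(z, -700.0))
    return e / (1.0 + e)


@dataclass(frozen=True)
class Moments:
    """First three raw moments of a nonnegative duration (min, min^2, min^3)."""

    m1: float
    m2: float
    m3: float

    def __post_init__(self) -> None:
        if not (self.m1 > 0.0 and math.isfinite(self.m1)):
            raise InfeasibleMomentsError(f"m1 must be positive, got {self.m1!r}")
        if self.m2 < self.m1 ** 2 * (1.0 - 1e-12):
            raise InfeasibleMomentsError(
                f"negative variance: m2={self.m2!r} < m1^2={self.m1**2!r}")
        # Cauchy-Schwarz for nonnegative variables: E[X^3] E[X] >= E[X^2]^2
        if self.m3 * self.m1 < self.m2 ** 2 * (1.0 - 1e-9):
            raise InfeasibleMomentsError(
                f"moment triple ({self.m1}, {self.m2}, {self.m3}) violates "
                "E[X^3] E[X] >= E[X^2]^2")

    @property
    def scv(self) -> float:
        """Squared coefficient of variation."""
        return self.m2 / self.m1 ** 2 - 1.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m1, self.m2, self.m3)


@dataclass(frozen=True)
class ECParams:
    """Erlang–Coxian parameters and the induced exponential transition rates.

    ``n_ec`` counts all phases; ``n_ec - 2`` of them are Erlang phases with
    rate ``lambda_y`` (the first carrying an early-exit branch with
    probability ``1 - p_ec``), followed by a two-phase Coxian with rates
    ``lambda_x1``, ``lambda_x2`` and continuation probability ``p_x``.  The
    ``t`` attributes are the per-transition exponential rates used when the
    distribution is embedded in a Markov chain.
    """

    p_ec: float
    n_ec: int
    lambda_y: float
    p_x: float
    lambda_x1: float
    lambda_x2: float
    alpha: Optional[tuple[float, ...]] = None  # entry distribution over phases

    def __post_init__(self) -> None:
        if self.alpha is not None:
            a = np.asarray(self.alpha)
            if np.min(a) < -_PROB_TOL or abs(a.sum() - 1.0) > 1e-9:
                raise InfeasibleMomentsError(
                    "entry vector must be a probability distribution")
        for name in ("p_ec", "p_x"):
            v = getattr(self, name)
            if not -_PROB_TOL <= v <= 1.0 + _PROB_TOL:
                raise InfeasibleMomentsError(f"{name}={v!r} outside [0, 1]")
        for name in ("lambda_y", "lambda_x1", "lambda_x2"):
            if getattr(self, name) < 0.0:
                raise InfeasibleMomentsError(f"{name} must be >= 0")
        if self.n_ec < 2:
            raise InfeasibleMomentsError("n_ec must be at least 2")

    # transition rates, Erlang-Coxian identities
    @property
    def t0(self) -> float:
        return (1.0 - self.p_ec) * self.lambda_y

    @property
    def t01(self) -> float:
        return self.p_ec * self.lambda_y

    @property
    def t1(self) -> float:
        return (1.0 - self.p_x) * self.lambda_x1

    @property
    def t12(self) -> float:
        return self.p_x * self.lambda_x1

    @property
    def t2(self) -> float:
        return self.lambda_x2

    @property
    def n_phases(self) -> int:
        """Number of phases actually reachable (unreachable tail pruned)."""
        n = self.n_ec - 2 + 1
        if self.p_x > _PROB_TOL or self.alpha is not None:
            n += 1
        return n

    def entry_vector(self) -> np.ndarray:
        """Distribution over phases at the start of the sojourn."""
        n = self.n_phases
        if self.alpha is not None:
            a = np.clip(np.asarray(self.alpha, dtype=float), 0.0, None)
            return a / a.sum()
        a = np.zeros(n)
        a[0] = 1.0
        return a

    def subgenerator(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(T, exit)``: transient generator and absorption rates.

        The Coxian second phase is pruned when ``p_x == 0`` and no entry
        mass reaches it, so that ``T`` stays invertible.
        """
        k_erl = self.n_ec - 2
        use_x2 = self.p_x > _PROB_TOL or self.alpha is not None
        n = k_erl + 1 + (1 if use_x2 else 0)
        T = np.zeros((n, n))
        exit_rates = np.zeros(n)
        for i in range(k_erl):
            rate = self.lambda_y
            T[i, i] = -rate
            if i == 0:
                exit_rates[i] = self.t0
                T[i, i + 1] = self.t01
            else:
                T[i, i + 1] = rate
        ix1 = k_erl
        T[ix1, ix1] = -self.lambda_x1
        exit_rates[ix1] = self.t1 if use_x2 else self.lambda_x1
        if use_x2:
            T[ix1, ix1 + 1] = self.t12
            T[ix1 + 1, ix1 + 1] = -self.lambda_x2
            exit_rates[ix1 + 1] = self.lambda_x2
        return T, exit_rates


def phase_type_moments(p: ECParams) -> Moments:
    """Exact first three raw moments of the EC distribution.

    Uses the absorption-time identity ``E[X^k] = k! * alpha (-T)^{-k} 1``.
    """
    T, _ = p.subgenerator()
    n = T.shape[0]
    alpha = p.entry_vector()
    ones = np.ones(n)
    neg_t_inv = np.linalg.inv(-T)
    v1 = neg_t_inv @ ones
    v2 = neg_t_inv @ v1
    v3 = neg_t_inv @ v2
    return Moments(float(alpha @ v1), 2.0 * float(alpha @ v2),
                   6.0 * float(alpha @ v3))


def _try_coxian2(m: Moments) -> ECParams | None:
    """Closed-form two-phase Coxian match, or None when outside its region."""
    scale = m.m1
    m1, h2, h3 = 1.0, m.m2 / (2.0 * scale ** 2), m.m3 / (6.0 * scale ** 3)
    # exponential special case: both relative moments at their exponential value
    if abs(h2 - 1.0) < 1e-12 and abs(h3 - 1.0) < 1e-10:
        rate = 1.0 / scale
        return ECParams(p_ec=1.0, n_ec=2, lambda_y=0.0, p_x=0.0,
                        lambda_x1=rate, lambda_x2=rate)
    c2 = h2 - m1 ** 2
    c1 = m1 * h2 - h3
    c0 = m1 * h3 - h2 ** 2
    if abs(c2) < 1e-14:
        roots = [] if abs(c1) < 1e-14 else [-c0 / c1]
    else:
        disc = c1 ** 2 - 4.0 * c2 * c0
        if disc < 0.0:
            return None
        sq = math.sqrt(disc)
        roots = [(-c1 + sq) / (2.0 * c2), (-c1 - sq) / (2.0 * c2)]
    best: ECParams | None = None
    for a_mean in roots:
        if not (0.0 < a_mean and math.isfinite(a_mean)):
            continue
        denom = a_mean - m1
        if abs(denom) < 1e-14:
            continue
        b_mean = (a_mean * m1 - h2) / denom
        if not (b_mean > 0.0 and math.isfinite(b_mean)):
            continue
        p = (m1 - a_mean) / b_mean
        if not -_PROB_TOL <= p <= 1.0 + _PROB_TOL:
            continue
        p = min(max(p, 0.0), 1.0)
        cand = ECParams(p_ec=1.0, n_ec=2, lambda_y=0.0, p_x=p,
                        lambda_x1=1.0 / (a_mean * scale),
                        lambda_x2=1.0 / (b_mean * scale))
        if _roundtrip_ok(cand, m):
            if best is None or cand.lambda_x1 >= best.lambda_x1:
                best = cand
    return best


def _roundtrip_ok(p: ECParams, m: Moments, rtol: float = _FIT_RTOL) -> bool:
    got = phase_type_moments(p)
    return all(abs(g - t) <= rtol * abs(t)
               for g, t in zip(got.as_tuple(), m.as_tuple()))


def needs_erlang_stage(m: Moments) -> bool:
    """True iff the moment triple lies outside the two-phase-Coxian region."""
    return _try_coxian2(m) is None


def fit_coxian2(m: Moments) -> ECParams:
    """Exact two-phase Coxian three-moment match.

    Raises :class:`InfeasibleMomentsError` when the triple lies outside the
    Coxian-2 region (use :func:`fit_ec` there).
    """
    fit = _try_coxian2(m)
    if fit is None:
        raise InfeasibleMomentsError(
            f"moments {m.as_tuple()} are not two-phase-Coxian representable")
    return fit


def _ec_moments_numeric(k_erl: int, lam_y: float, p_x: float,
                        lam_x1: float, lam_x2: float,
                        p_ec: float = 1.0) -> tuple[float, float, float]:
    """Raw moments of the EC family without building matrices.

    The distribution is ``exp(lam_y)`` (first Erlang phase, present when
    ``k_erl > 0``) followed with probability ``p_ec`` by the remaining
    ``k_erl - 1`` Erlang phases and the two-phase Coxian; with probability
    ``1 - p_ec`` it ends after the first phase.
    """
    # Coxian-2 raw moments
    A = 1.0 / lam_x1
    Bm = 1.0 / lam_x2 if lam_x2 > 0 else 0.0
    c1 = A + p_x * Bm
    c2 = 2.0 * (A * A + p_x * Bm * (A + Bm))
    c3 = 6.0 * (A ** 3 + p_x * Bm * (A * A + A * Bm + Bm * Bm))
    if k_erl == 0:
        return c1, c2, c3
    if k_erl > 1:   # remaining Erlang phases, entered together with the Coxian
        e1 = (k_erl - 1) / lam_y
        e2 = (k_erl - 1) * k_erl / lam_y ** 2
        e3 = (k_erl - 1) * k_erl * (k_erl + 1) / lam_y ** 3
        c1, c2, c3 = (e1 + c1, e2 + 2.0 * e1 * c1 + c2,
                      e3 + 3.0 * e2 * c1 + 3.0 * e1 * c2 + c3)
    # first phase with early-exit branch
    f1, f2, f3 = 1.0 / lam_y, 2.0 / lam_y ** 2, 6.0 / lam_y ** 3
    m1 = f1 + p_ec * c1
    m2 = f2 + 2.0 * p_ec * f1 * c1 + p_ec * c2
    m3 = f3 + 3.0 * f2 * p_ec * c1 + 3.0 * f1 * p_ec * c2 + p_ec * c3
    return m1, m2, m3


def fit_ec(m: Moments) -> ECParams:
    """Full Erlang–Coxian three-moment fit.

    Delegates to :func:`fit_coxian2` inside the Coxian-2 region; otherwise
    prepends Erlang phases (smallest count that admits an exact match) and
    solves the moment equations numerically.  The result always round-trips
    its target moments through :func:`phase_type_moments` to ``1e-8``
    relative accuracy.
    """
    cox = _try_coxian2(m)
    if cox is not None:
        return cox

    scale = m.m1
    target = np.array([1.0, m.m2 / scale ** 2, m.m3 / scale ** 3])
    scv = m.scv
    # minimum Erlang-phase count suggested by the variance: Erlang-n has scv 1/n
    k_min = max(1, int(math.ceil(1.0 / max(scv, 1e-9))) - 2)
    for k_erl in range(k_min, k_min + 6):
        n_total = k_erl + 2

        def _clip_exp(v: float) -> float:
            return math.exp(min(max(v, -50.0), 50.0))

        def resid_branch(x: np.ndarray, k: int = k_erl) -> np.ndarray:
            # shared Coxian rate, free continuation probability
            got = _ec_moments_numeric(k, _clip_exp(x[0]), _expit(x[2]),
                                      _clip_exp(x[1]), _clip_exp(x[1]))
            return np.asarray(got) / target - 1.0

        def resid_chain(x: np.ndarray, k: int = k_erl) -> np.ndarray:
            # pure hypoexponential chain: p_x = 1, distinct tail rates
            got = _ec_moments_numeric(k, _clip_exp(x[0]), 1.0,
                                      _clip_exp(x[1]), _clip_exp(x[2]))
            return np.asarray(got) / target - 1.0

        def resid_exit(x: np.ndarray, k: int = k_erl) -> np.ndarray:
            # early-exit branch after the first phase (p_ec free, p_x = 1)
            got = _ec_moments_numeric(k, _clip_exp(x[0]), 1.0,
                                      _clip_exp(x[1]), _clip_exp(x[1]),
                                      p_ec=_expit(x[2]))
            return np.asarray(got) / target - 1.0

        def unpack(variant: str, x: np.ndarray) -> ECParams:
            lam_y = _clip_exp(x[0]) / scale
            if variant == "branch":
                return ECParams(p_ec=1.0, n_ec=n_total, lambda_y=lam_y,
                                p_x=_expit(x[2]),
                                lambda_x1=_clip_exp(x[1]) / scale,
                                lambda_x2=_clip_exp(x[1]) / scale)
            if variant == "chain":
                return ECParams(p_ec=1.0, n_ec=n_total, lambda_y=lam_y,
                                p_x=1.0,
                                lambda_x1=_clip_exp(x[1]) / scale,
                                lambda_x2=_clip_exp(x[2]) / scale)
            return ECParams(p_ec=_expit(x[2]), n_ec=n_total, lambda_y=lam_y,
                            p_x=1.0,
                            lambda_x1=_clip_exp(x[1]) / scale,
                            lambda_x2=_clip_exp(x[1]) / scale)

        residuals = {"branch": resid_branch, "chain": resid_chain,
                     "exit": resid_exit}
        # initial guesses: spread the mean between the Erlang run and the tail
        for share in (0.5, 0.3, 0.7, 0.9, 0.1):
            lam_y0 = k_erl / max(share, 1e-3)
            lam_x0 = 1.5 / max(1.0 - share, 1e-3)
            for variant, x0 in (
                ("branch", np.array([math.log(lam_y0), math.log(lam_x0), 0.0])),
                ("chain", np.array([math.log(lam_y0), math.log(2.0 * lam_x0),
                                    math.log(2.0 * lam_x0) + 0.1])),
                ("exit", np.array([math.log(lam_y0), math.log(lam_x0), 1.0])),
            ):
                sol = optimize.root(residuals[variant], x0, method="hybr",
                                    tol=1e-14)
                if not sol.success or np.max(np.abs(sol.fun)) > 1e-10:
                    continue
                cand = unpack(variant, sol.x)
                if _roundtrip_ok(cand, m):
                    return cand

        # full five-parameter family, under-determined: least-squares root find
        def resid_full(x: np.ndarray, k: int = k_erl) -> np.ndarray:
            got = _ec_moments_numeric(k, _clip_exp(x[0]), _expit(x[3]),
                                      _clip_exp(x[1]), _clip_exp(x[2]),
                                      p_ec=_expit(x[4]))
            return np.asarray(got) / target - 1.0

        for share in (0.5,):
            lam_y0 = k_erl / max(share, 1e-3)
            lam_x0 = 1.5 / max(1.0 - share, 1e-3)
            x0 = np.array([math.log(lam_y0), math.log(lam_x0),
                           math.log(3.0 * lam_x0), 1.0, 2.0])
            sol = optimize.least_squares(resid_full, x0, xtol=1e-15,
                                         ftol=1e-15, gtol=1e-15)
            if np.max(np.abs(sol.fun)) > 1e-10:
                continue
            cand = ECParams(p_ec=_expit(sol.x[4]), n_ec=n_total,
                            lambda_y=_clip_exp(sol.x[0]) / scale,
                            p_x=_expit(sol.x[3]),
                            lambda_x1=_clip_exp(sol.x[1]) / scale,
                            lambda_x2=_clip_exp(sol.x[2]) / scale)
            if _roundtrip_ok(cand, m):
                return cand

    # last resort: acyclic series chain with a free entry vector, i.e. the
    # sojourn may begin part-way down the Erlang-Coxian phase chain
    fit = _fit_series_aph(m)
    if fit is not None:
        return fit
    raise InfeasibleMomentsError(
        f"no Erlang–Coxian fit found for moments {m.as_tuple()}")


def _fit_series_aph(m: Moments) -> ECParams | None:
    """Fit a forward chain exp(l_1) -> ... -> exp(l_n) -> absorb whose entry
    phase is random.  Covers the low-third-moment region that single-entry
    Erlang–Coxian shapes miss."""
    scale = m.m1
    target = np.array([1.0, m.m2 / scale ** 2, m.m3 / scale ** 3])
    rng = np.random.default_rng(12345)
    for n in (3, 4, 5, 6, 8):
        k_erl = n - 2

        def resid(x: np.ndarray, n_ph: int = n, k: int = k_erl) -> np.ndarray:
            lam_y = math.exp(min(max(x[0], -40.0), 40.0))
            lam_x1 = math.exp(min(max(x[1], -40.0), 40.0))
            lam_x2 = math.exp(min(max(x[2], -40.0), 40.0))
            z = np.concatenate([x[3:], [0.0]])
            a = np.exp(z - np.max(z))
            a /= a.sum()
            lams = np.array([lam_y] * k + [lam_x1, lam_x2])
            T = np.diag(-lams)
            for i in range(n_ph - 1):
                T[i, i + 1] = lams[i]
            inv = np.linalg.inv(-T)
            o = np.ones(n_ph)
            got = np.array([a @ inv @ o, 2.0 * a @ (inv @ inv @ o),
                            6.0 * a @ (inv @ inv @ inv @ o)])
            return got / target - 1.0

        for trial in range(25):
            x0 = np.concatenate([rng.normal(0.5, 1.0, 3),
                                 rng.normal(0.0, 1.0, n - 1)])
            sol = optimize.least_squares(resid, x0, xtol=1e-15, ftol=1e-15,
                                         gtol=1e-15)
            if np.max(np.abs(sol.fun)) > 1e-10:
                continue
            z = np.concatenate([sol.x[3:], [0.0]])
            a = np.exp(z - np.max(z))
            a /= a.sum()
            cand = ECParams(
                p_ec=1.0, n_ec=n,
                lambda_y=math.exp(min(max(sol.x[0], -40.0), 40.0)) / scale,
                p_x=1.0,
                lambda_x1=math.exp(min(max(sol.x[1], -40.0), 40.0)) / scale,
                lambda_x2=math.exp(min(max(sol.x[2], -40.0), 40.0)) / scale,
                alpha=tuple(a))
            if _roundtrip_ok(cand, m):
                return cand
    return None


def sample_phase_type(p: ECParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws from the fitted distribution (vectorized forward
    walk over the acyclic phase chain)."""
    T, exit_rates = p.subgenerator()
    n_ph = T.shape[0]
    alpha = p.entry_vector()
    phase = rng.choice(n_ph, size=n, p=alpha)
    out = np.zeros(n)
    for i in range(n_ph):
        mask = phase == i
        k = int(mask.sum())
        if k == 0:
            continue
        rate = -T[i, i]
        out[mask] += rng.exponential(1.0 / rate, size=k)
        # absorb or move forward
        p_abs = exit_rates[i] / rate
        absorbed = rng.random(k) < p_abs
        idx = np.where(mask)[0]
        phase[idx[absorbed]] = n_ph          # done
        if i + 1 < n_ph:
            # forward targets: split remaining mass among T[i, j>i]
            rem = idx[~absorbed]
            if rem.size:
                probs = T[i, i + 1:].clip(min=0.0)
                tot = probs.sum()
                if tot <= 0:
                    phase[rem] = n_ph
                else:
                    phase[rem] = i + 1 + rng.choice(
                        n_ph - i - 1, size=rem.size, p=probs / tot)
        else:
            phase[idx[~absorbed]] = n_ph
    return out
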