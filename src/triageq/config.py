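"""Workflow configuration and derived per-class rates.

A radiology reading queue is described by the fraction ``f`` of interrupting
images, the disease prevalence ``pi`` among non-interrupting images, the
triage device's sensitivity/specificity, the number of radiologists, mean
read times per subgroup (minutes), and the load given either as a total
arrival rate ``lambda`` (per minute) or as a traffic intensity ``rho``.

From these, every per-class Poisson arrival rate and mean reading rate that
the queueing models consume is derived:

* ``lambda_f = f * lambda`` and ``lambda_nonf = (1 - f) * lambda``;
* ``lambda_+ = [pi Se + (1 - pi)(1 - Sp)] * lambda`` (AI-positive) and its
  AI-negative complement;
* hyperexponential mean read times ``1/mu_nonf = pi/mu_D + (1 - pi)/mu_ND``
  and the PPV/NPV-weighted analogues for the AI-positive and AI-negative
  classes.

All times are minutes; all rates are per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import ConfigError

__all__ = [
    "WorkflowConfig",
    "DerivedRates",
    "OperatingPoint",
    "validate_config",
    "lambda_from_rho",
    "effective_service_rate",
    "derive_rates",
    "ppv_npv",
]


@dataclass(frozen=True)
class WorkflowConfig:
    """Clinical scenario parameters.

    Parameters
    ----------
    f : float
        Fraction of interrupting images among all arrivals, in ``[0, 1)``.
    prevalence_pi : float
        Disease prevalence among non-interrupting images, in ``(0, 1)``.
    se, sp : float
        Sensitivity and specificity of the triage device, in ``[0, 1]``.
    n_rad : int
        Number of radiologists (servers), at least 1.
    read_time_interrupting : float
        Mean read time ``1/mu_f`` of an interrupting image, minutes.
    read_time_diseased, read_time_nondiseased : float
        Mean read times ``1/mu_D`` and ``1/mu_ND``, minutes.
    lambda_total : float, optional
        Total Poisson arrival rate, per minute.  Exactly one of
        ``lambda_total`` and ``rho`` must be given.
    rho : float, optional
        Traffic intensity in ``(0, 1)``; converted to an arrival rate via
        :func:`lambda_from_rho`.
    """

    f: float
    prevalence_pi: float
    se: float
    sp: float
    n_rad: int = 1
    read_time_interrupting: float = 5.0
    read_time_diseased: float = 10.0
    read_time_nondiseased: float = 10.0
    lambda_total: Optional[float] = None
    rho: Optional[float] = None

    @property
    def mu_f(self) -> float:
        return 1.0 / self.read_time_interrupting

    @property
    def mu_d(self) -> float:
        return 1.0 / self.read_time_diseased

    @property
    def mu_nd(self) -> float:
        return 1.0 / self.read_time_nondiseased

    @property
    def equal_read_rates(self) -> bool:
        return math.isclose(self.read_time_diseased, self.read_time_nondiseased,
                            rel_tol=1e-12, abs_tol=0.0)


@dataclass(frozen=True)
class DerivedRates:
    """All per-class arrival and service rates plus predictive values."""

    lambda_total: float
    lambda_f: float
    lambda_nonf: float
    lambda_pos: float
    lambda_neg: float
    mu_f: float
    mu_d: float
    mu_nd: float
    mu_nonf: float
    mu_pos: float
    mu_neg: float
    ppv: float
    npv: float


@dataclass(frozen=True)
class OperatingPoint:
    """A point in ROC space: ``tpr = Se``, ``fpr = 1 - Sp``."""

    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        for name in ("tpr", "fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")

    @property
    def se(self) -> float:
        return self.tpr

    @property
    def sp(self) -> float:
        return 1.0 - self.fpr


def validate_config(cfg: WorkflowConfig) -> WorkflowConfig:
    """Validate a :class:`WorkflowConfig`, returning a normalized copy.

    The returned config always carries ``lambda_total`` (converting from
    ``rho`` if needed) while preserving ``rho`` when that was the input.

    Raises
    ------
    ConfigError
        On non-positive read times, probabilities outside their ranges,
        ``f >= 1``, ``rho`` outside ``(0, 1)``, or when both / neither of
        the load fields are set.
    """
    if not 0.0 <= cfg.f < 1.0:
        raise ConfigError(f"interrupting fraction f must lie in [0, 1), got {cfg.f!r}")
    if not 0.0 < cfg.prevalence_pi < 1.0:
        raise ConfigError(
            f"prevalence must lie in (0, 1), got {cfg.prevalence_pi!r}")
    for name in ("se", "sp"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
    if int(cfg.n_rad) != cfg.n_rad or cfg.n_rad < 1:
        raise ConfigError(f"n_rad must be an integer >= 1, got {cfg.n_rad!r}")
    for name in ("read_time_interrupting", "read_time_diseased",
                 "read_time_nondiseased"):
        v = getattr(cfg, name)
        if not (v > 0.0 and math.isfinite(v)):
            raise ConfigError(f"{name} must be a positive time in minutes, got {v!r}")
    has_lambda = cfg.lambda_total is not None
    has_rho = cfg.rho is not None
    if not has_lambda and not has_rho:
        raise ConfigError(
            "exactly one of lambda_total and rho must be provided")
    if has_lambda and has_rho:
        # permitted only for an already-normalized config
        implied = lambda_from_rho(cfg)
        if not math.isclose(cfg.lambda_total, implied, rel_tol=1e-9):
            raise ConfigError(
                "exactly one of lambda_total and rho must be provided "
                f"(got inconsistent lambda_total={cfg.lambda_total!r} and "
                f"rho={cfg.rho!r})")
    if has_rho and not 0.0 < cfg.rho < 1.0:
        raise ConfigError(f"rho must lie in (0, 1) for a stable system, got {cfg.rho!r}")
    if has_lambda and not (cfg.lambda_total > 0.0 and math.isfinite(cfg.lambda_total)):
        raise ConfigError(f"lambda_total must be positive, got {cfg.lambda_total!r}")
    if has_rho:
        cfg = replace(cfg, lambda_total=lambda_from_rho(cfg))
    return cfg


def effective_service_rate(cfg: WorkflowConfig) -> float:
    """Overall mean reading rate ``mu_eff``.

    ``1/mu_eff`` is the arrival-fraction-weighted mean read time
    ``f/mu_f + (1 - f)(pi/mu_D + (1 - pi)/mu_ND)``, i.e. the mean read time
    of a randomly chosen arrival.  This is the ``mu`` entering the traffic
    intensity ``rho = lambda / (mu N_rad)``.
    """
    mean_nonf = (cfg.prevalence_pi * cfg.read_time_diseased
                 + (1.0 - cfg.prevalence_pi) * cfg.read_time_nondiseased)
    mean_read = cfg.f * cfg.read_time_interrupting + (1.0 - cfg.f) * mean_nonf
    return 1.0 / mean_read


def lambda_from_rho(cfg: WorkflowConfig) -> float:
    """Arrival rate implied by the traffic intensity: ``rho * mu_eff * N_rad``."""
    if cfg.rho is None:
        raise ConfigError("config has no rho to convert")
    return cfg.rho * effective_service_rate(cfg) * cfg.n_rad


def traffic_intensity(cfg: WorkflowConfig) -> float:
    """``rho = lambda / (mu_eff N_rad)`` for a validated config."""
    if cfg.rho is not None:
        return cfg.rho
    if cfg.lambda_total is None:
        raise ConfigError("config has neither rho nor lambda_total")
    return cfg.lambda_total / (effective_service_rate(cfg) * cfg.n_rad)


def ppv_npv(pi: float, se: float, sp: float) -> tuple[float, float]:
    """Positive and negative predictive values by Bayes' rule.

    ``ppv = pi Se / (pi Se + (1-pi)(1-Sp))`` and
    ``npv = (1-pi) Sp / ((1-pi) Sp + pi (1-Se))``.  A zero denominator
    (an empty AI-positive or AI-negative class) yields 0 by convention;
    downstream weights on the empty class are themselves 0, so the value
    never contributes.
    """
    pos = pi * se + (1.0 - pi) * (1.0 - sp)
    neg = pi * (1.0 - se) + (1.0 - pi) * sp
    ppv = pi * se / pos if pos > 0.0 else 0.0
    npv = (1.0 - pi) * sp / neg if neg > 0.0 else 0.0
    return ppv, npv


def derive_rates(cfg: WorkflowConfig) -> DerivedRates:
    """Populate every per-class arrival and reading rate for a validated config."""
    cfg = validate_config(cfg)
    lam = cfg.lambda_total
    lam_f = cfg.f * lam
    lam_nonf = (1.0 - cfg.f) * lam
    pi = cfg.prevalence_pi
    # class membership fractions among non-interrupting images
    frac_pos = pi * cfg.se + (1.0 - pi) * (1.0 - cfg.sp)
    lam_pos = frac_pos * lam_nonf
    lam_neg = lam_nonf - lam_pos
    ppv, npv = ppv_npv(pi, cfg.se, cfg.sp)

    mean_nonf = pi * cfg.read_time_diseased + (1.0 - pi) * cfg.read_time_nondiseased
    mean_pos = (ppv * cfg.read_time_diseased
                + (1.0 - ppv) * cfg.read_time_nondiseased)
    mean_neg = ((1.0 - npv) * cfg.read_time_diseased
                + npv * cfg.read_time_nondiseased)
    return DerivedRates(
        lambda_total=lam,
        lambda_f=lam_f,
        lambda_nonf=lam_nonf,
        lambda_pos=lam_pos,
        lambda_neg=lam_neg,
        mu_f=cfg.mu_f,
        mu_d=cfg.mu_d,
        mu_nd=cfg.mu_nd,
        mu_nonf=1.0 / mean_nonf,
        mu_pos=1.0 / mean_pos,
        mu_neg=1.0 / mean_neg,
        ppv=ppv,
        npv=npv,
    )
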