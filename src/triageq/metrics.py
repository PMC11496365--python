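"""Diseased / non-diseased wait-time-saving metrics.

Without a triage device every non-interrupting image waits the same on
average, so the diseased mean wait equals the non-interrupting class wait.
With the device, diseased images split into true positives (weight ``Se``)
and false negatives (weight ``1 - Se``):

    W_D^CADt  = W_+ * Se + W_- * (1 - Se)
    W_ND^CADt = W_+ * (1 - Sp) + W_- * Sp

The performance metric is the signed difference
``delta W = W^CADt - W^no-CADt`` (minutes); negative values mean the
diseased subgroup is, on average, read sooner with the device deployed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .models import ScenarioWaits

__all__ = [
    "MetricResult",
    "diseased_wait_with_cadt",
    "nondiseased_wait_with_cadt",
    "delta_metrics",
]


@dataclass(frozen=True)
class MetricResult:
    """Mean waits (minutes) and their with/without differences."""

    w_d_no_cadt: float
    w_d_cadt: float
    delta_w_d: float
    w_nd_no_cadt: float
    w_nd_cadt: float
    delta_w_nd: float
    ratio_d: Optional[float] = None   # supplementary: W_D^CADt / W_D^no-CADt

    def to_dict(self) -> dict:
        return {
            "w_d_no_cadt_min": self.w_d_no_cadt,
            "w_d_cadt_min": self.w_d_cadt,
            "delta_w_d_min": self.delta_w_d,
            "w_nd_no_cadt_min": self.w_nd_no_cadt,
            "w_nd_cadt_min": self.w_nd_cadt,
            "delta_w_nd_min": self.delta_w_nd,
            "ratio_d": self.ratio_d,
        }


def diseased_wait_with_cadt(w_pos: float, w_neg: float, se: float) -> float:
    """Mean diseased wait with the device: ``W_+ Se + W_- (1 - Se)``."""
    return w_pos * se + w_neg * (1.0 - se)


def nondiseased_wait_with_cadt(w_pos: float, w_neg: float, sp: float) -> float:
    """Mean non-diseased wait with the device: ``W_+ (1 - Sp) + W_- Sp``."""
    return w_pos * (1.0 - sp) + w_neg * sp


def delta_metrics(without: ScenarioWaits, with_cadt: ScenarioWaits,
                  se: float, sp: float) -> MetricResult:
    """Combine per-class waits from both scenarios into the saving metrics."""
    w_base = without.w_q_nonf
    w_pos = with_cadt.w_q_pos
    w_neg = with_cadt.w_q_neg
    w_d = diseased_wait_with_cadt(w_pos, w_neg, se)
    w_nd = nondiseased_wait_with_cadt(w_pos, w_neg, sp)
    return MetricResult(
        w_d_no_cadt=w_base,
        w_d_cadt=w_d,
        delta_w_d=w_d - w_base,
        w_nd_no_cadt=w_base,
        w_nd_cadt=w_nd,
        delta_w_nd=w_nd - w_base,
        ratio_d=(w_d / w_base) if w_base > 0.0 else None,
    )
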