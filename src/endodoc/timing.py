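"""Withdrawal, insertion and intervention times, plus evaluation statistics.

The six durations follow the annotation scheme used for video-based
withdrawal-time measurement::

    t_insertion              = t_first_cecum - t_enter_body
    t_cecum_inspection       = t_last_cecum  - t_first_cecum
    t_withdrawal             = t_exit_body   - t_last_cecum
    t_intervention_total     = sum over intervention intervals
    t_cecum_inspection_corrected = t_cecum_inspection
                                   - intervention time within the cecum phase
    t_withdrawal_corrected   = t_withdrawal
                                   - intervention time within withdrawal

Withdrawal time here is the ESGE quality metric: time spent withdrawing the
endoscope from cecum to anal canal while inspecting the mucosa; the
corrected variant subtracts time spent on endoscopic interventions, which
would otherwise inflate the metric.  Interventions during insertion count
toward ``t_intervention_total`` but correct neither phase.

The evaluation helpers implement the arithmetic used to compare predicted
against measured withdrawal times (absolute differences, their median, a
strict >20 % relative-divergence flag) and the percentage summaries used to
grade automatically selected report images (specificity, representation
rate), rounded half-up to one decimal as conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import (
    EmptyInput,
    InvalidTimeline,
    NonPositiveMeasurement,
    ZeroDenominator,
    ZeroPredicted,
)
from .segmentation import ExamTimeline

__all__ = [
    "TimingSummary",
    "EvaluationResult",
    "compute_times",
    "withdrawal_divergence",
    "summarize_differences",
    "selection_specificity",
    "representation_rate",
    "reported_withdrawal_time",
]

_SUM_TOL = 1e-6


def _round_half_up(value: Decimal, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def _minutes(seconds: float) -> float:
    return _round_half_up(Decimal(repr(seconds)) / Decimal(60), 1)


@dataclass(frozen=True)
class TimingSummary:
    """The six exam durations, in seconds."""

    t_insertion: float
    t_cecum_inspection: float
    t_withdrawal: float
    t_intervention_total: float
    t_cecum_inspection_corrected: float
    t_withdrawal_corrected: float

    def __post_init__(self) -> None:
        for name in ("t_insertion", "t_cecum_inspection", "t_withdrawal",
                     "t_intervention_total", "t_cecum_inspection_corrected",
                     "t_withdrawal_corrected"):
            if getattr(self, name) < -_SUM_TOL:
                raise InvalidTimeline(f"{name} is negative")
        if self.t_cecum_inspection_corrected > \
                self.t_cecum_inspection + _SUM_TOL:
            raise InvalidTimeline("corrected cecum time exceeds uncorrected")
        if self.t_withdrawal_corrected > self.t_withdrawal + _SUM_TOL:
            raise InvalidTimeline("corrected withdrawal exceeds uncorrected")

    def to_json_dict(self) -> dict:
        """Both seconds (3 decimals) and minutes (1 decimal) per field."""
        out = {}
        for name in ("t_insertion", "t_cecum_inspection", "t_withdrawal",
                     "t_intervention_total", "t_cecum_inspection_corrected",
                     "t_withdrawal_corrected"):
            seconds = getattr(self, name)
            out[name] = {"seconds": round(seconds, 3),
                         "minutes": _minutes(seconds)}
        return out


@dataclass(frozen=True)
class EvaluationResult:
    """Per-exam absolute differences and divergence-flag counts."""

    abs_diffs_s: tuple[float, ...]
    median_abs_diff_s: float
    n_flagged: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_flagged <= self.n_total):
            raise ValueError("flag count outside [0, n_total]")
        if self.median_abs_diff_s < 0:
            raise ValueError("median absolute difference is negative")

    def to_json_dict(self) -> dict:
        return {"median_abs_diff_s": round(self.median_abs_diff_s, 3),
                "median_abs_diff_min": _minutes(self.median_abs_diff_s),
                "n_flagged": self.n_flagged,
                "n_total": self.n_total}


# ---------------------------------------------------------------------------
# durations
# ---------------------------------------------------------------------------

def _overlap_s(intervals: Sequence[tuple[float, float]],
               lo: float, hi: float) -> float:
    """Total length of ``intervals`` intersected with ``[lo, hi)``."""
    return sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in intervals)


def compute_times(timeline: ExamTimeline) -> TimingSummary:
    """The six durations of a segmented exam.

    Corrections subtract, per phase, only the intervention time overlapping
    that phase, so an intervention straddling the cecum/withdrawal boundary
    is split between the two corrected durations.
    """
    anchors = (timeline.t_enter_body, timeline.t_first_cecum,
               timeline.t_last_cecum, timeline.t_exit_body)
    if any(b < a for a, b in zip(anchors, anchors[1:])):
        raise InvalidTimeline(f"anchors out of order: {anchors}")
    t_insertion = timeline.t_first_cecum - timeline.t_enter_body
    t_cecum = timeline.t_last_cecum - timeline.t_first_cecum
    t_withdrawal = timeline.t_exit_body - timeline.t_last_cecum
    total = sum(e - s for s, e in timeline.interventions)
    cecum_corr = _overlap_s(timeline.interventions,
                            timeline.t_first_cecum, timeline.t_last_cecum)
    withdrawal_corr = _overlap_s(timeline.interventions,
                                 timeline.t_last_cecum, timeline.t_exit_body)
    return TimingSummary(
        t_insertion=t_insertion,
        t_cecum_inspection=t_cecum,
        t_withdrawal=t_withdrawal,
        t_intervention_total=total,
        t_cecum_inspection_corrected=t_cecum - cecum_corr,
        t_withdrawal_corrected=t_withdrawal - withdrawal_corr,
    )


def reported_withdrawal_time(t_last_cecal_image_s: float,
                             t_rectal_image_s: float) -> float:
    """Fallback estimate from two photo timestamps (rectal − cecal).

    Emulates deriving a reported withdrawal time from the timestamps of the
    last documented cecal image and the rectal image when the report states
    no time.  Purely a subtraction helper; the pipeline itself does not use
    it.
    """
    if t_rectal_image_s < t_last_cecal_image_s:
        raise InvalidTimeline("rectal image precedes the cecal image")
    return t_rectal_image_s - t_last_cecal_image_s


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def withdrawal_divergence(predicted_s: float, measured_s: float,
                          threshold: float = 0.20,
                          ) -> tuple[float, bool]:
    """Relative divergence |predicted − measured| / measured and its flag.

    The flag is strict: an exam diverging by exactly the threshold is not
    flagged ("more than" 20 %).
    """
    if measured_s <= 0:
        raise NonPositiveMeasurement(f"measured_s={measured_s}")
    rel = abs(predicted_s - measured_s) / measured_s
    return rel, rel > threshold


def summarize_differences(pairs: Sequence[tuple[float, float]],
                          threshold: float = 0.20) -> EvaluationResult:
    """Absolute differences, their median, and divergence-flag counts.

    The median uses the midpoint of the two central order statistics for
    even sample sizes.
    """
    if not pairs:
        raise EmptyInput("no (predicted, measured) pairs")
    diffs = []
    n_flagged = 0
    for predicted, measured in pairs:
        _, flagged = withdrawal_divergence(predicted, measured, threshold)
        diffs.append(abs(predicted - measured))
        n_flagged += flagged
    ordered = sorted(diffs)
    n = len(ordered)
    if n % 2:
        median = ordered[n // 2]
    else:
        median = 0.5 * (ordered[n // 2 - 1] + ordered[n // 2])
    return EvaluationResult(abs_diffs_s=tuple(diffs),
                            median_abs_diff_s=median,
                            n_flagged=n_flagged, n_total=n)


def selection_specificity(n_containing: int, n_predicted: int) -> float:
    """Percent of predicted report images that truly contain their label.

    ``100 * n_containing / n_predicted`` rounded half-up to one decimal.
    """
    if n_containing < 0 or n_predicted < n_containing:
        raise ValueError("require n_predicted >= n_containing >= 0")
    if n_predicted == 0:
        raise ZeroPredicted("specificity undefined for zero predictions")
    return _round_half_up(Decimal(100 * n_containing) / Decimal(n_predicted))


def representation_rate(n_identified: int, n_documented: int) -> float:
    """Percent of documented events identifiable in the photodocumentation.

    ``100 * n_identified / n_documented`` rounded half-up to one decimal.
    """
    if n_documented <= 0:
        raise ZeroDenominator("representation rate needs n_documented > 0")
    if not (0 <= n_identified <= n_documented):
        raise ValueError("require 0 <= n_identified <= n_documented")
    return _round_half_up(Decimal(100 * n_identified) / Decimal(n_documented))
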