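"""Exam-phase segmentation from a multilabel confidence stream.

The segmentation turns noisy per-frame confidences into an
:class:`ExamTimeline`:

1. **Smoothing** — a centered moving average over frames within
   ±``window_s``/2 of each frame suppresses single-frame classifier noise.
2. **Binarization and run extraction** — each evidence signal (in-body,
   cecal landmark, intervention, polyp) is thresholded per label, and
   maximal True runs are extracted as half-open ``[start_s, end_s)``
   intervals; a run ends at the timestamp of the first frame after it, or at
   the end of the stream (last timestamp + one frame period).
3. **Sustain / merge / filter** — body and landmark runs must be sustained
   for at least ``min_sustain_s``; intervention and polyp runs are merged
   when separated by less than ``merge_gap_s``, then runs shorter than
   ``min_duration_s`` are dropped, then clipped to the body interval.

Anchors follow the annotation convention for withdrawal-time measurement:
``t_enter_body`` / ``t_exit_body`` delimit the in-body interval,
``t_first_cecum`` is the start of the first sustained landmark-evidence run
and ``t_last_cecum`` the end of the last one.  The base phases then tile the
recording: outside, insertion, cecum inspection, withdrawal, outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import PipelineConfig, validate_config
from .errors import (
    EmptyStream,
    InvalidTimeline,
    NegativeDuration,
    NoBodyDetected,
    NoCecumDetected,
)
from .stream import PredictionStream
from .taxonomy import (
    INTERVENTION_EVIDENCE_LABELS,
    LABEL_INDEX,
    LANDMARK_LABELS,
    PHASE_LABELS,
)

__all__ = [
    "PhaseSegment",
    "ExamTimeline",
    "smooth",
    "detect_body_interval",
    "detect_cecum_anchors",
    "detect_interventions",
    "segment_exam",
]

Interval = tuple[float, float]

_TILE_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSegment:
    """A half-open exam-phase interval ``[start_s, end_s)``."""

    phase: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.phase not in PHASE_LABELS:
            raise InvalidTimeline(f"unknown phase {self.phase!r}")
        if not self.start_s < self.end_s:
            raise InvalidTimeline(
                f"segment {self.phase}: start {self.start_s} >= "
                f"end {self.end_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ExamTimeline:
    """Anchor timestamps, base phase segments and intervention overlays.

    ``base_segments`` tile ``[0, end)`` of the recording without overlap
    (zero-length phases are omitted).  ``interventions`` and
    ``polyp_sequences`` are disjoint half-open overlays inside the body
    interval.
    """

    t_enter_body: float
    t_first_cecum: float
    t_last_cecum: float
    t_exit_body: float
    base_segments: tuple[PhaseSegment, ...]
    interventions: tuple[Interval, ...] = ()
    polyp_sequences: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        anchors = (self.t_enter_body, self.t_first_cecum,
                   self.t_last_cecum, self.t_exit_body)
        if any(b < a for a, b in zip(anchors, anchors[1:])):
            raise InvalidTimeline(f"anchors out of order: {anchors}")
        segs = self.base_segments
        if not segs:
            raise InvalidTimeline("timeline requires base segments")
        for prev, nxt in zip(segs, segs[1:]):
            if abs(prev.end_s - nxt.start_s) > _TILE_TOL:
                raise InvalidTimeline(
                    f"base segments do not tile: gap between {prev} and "
                    f"{nxt}")
        for start, end in self.interventions:
            if start < self.t_enter_body - _TILE_TOL \
                    or end > self.t_exit_body + _TILE_TOL:
                raise InvalidTimeline(
                    f"intervention ({start}, {end}) outside body interval")

    @property
    def end_s(self) -> float:
        return self.base_segments[-1].end_s

    @classmethod
    def from_anchors(cls,
                     t_enter_body: float,
                     t_first_cecum: float,
                     t_last_cecum: float,
                     t_exit_body: float,
                     end_s: float | None = None,
                     interventions: Sequence[Interval] = (),
                     polyp_sequences: Sequence[Interval] = (),
                     ) -> "ExamTimeline":
        """Build a timeline whose base segments tile [0, end_s)."""
        if end_s is None:
            end_s = t_exit_body
        bounds = [0.0, t_enter_body, t_first_cecum, t_last_cecum,
                  t_exit_body, end_s]
        phases = ["outside", "insertion", "cecum", "withdrawal", "outside"]
        segments = tuple(
            PhaseSegment(phase, start, end)
            for phase, start, end in zip(phases, bounds, bounds[1:])
            if end - start > _TILE_TOL)
        return cls(t_enter_body, t_first_cecum, t_last_cecum, t_exit_body,
                   segments, tuple(interventions), tuple(polyp_sequences))

    def to_json_dict(self) -> dict:
        return {
            "anchors": {
                "t_enter_body": round(self.t_enter_body, 3),
                "t_first_cecum": round(self.t_first_cecum, 3),
                "t_last_cecum": round(self.t_last_cecum, 3),
                "t_exit_body": round(self.t_exit_body, 3),
            },
            "segments": [{"phase": s.phase,
                          "start_s": round(s.start_s, 3),
                          "end_s": round(s.end_s, 3)}
                         for s in self.base_segments],
            "interventions": [[round(a, 3), round(b, 3)]
                              for a, b in self.interventions],
            "polyp_sequences": [[round(a, 3), round(b, 3)]
                                for a, b in self.polyp_sequences],
        }


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _window_mean(conf: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Mean confidence row over the frame slice ``[lo, hi)``.

    Shared by the offline and streaming paths so both produce bit-identical
    smoothed values.
    """
    return conf[lo:hi].mean(axis=0)


def smooth(stream: PredictionStream, window_s: float) -> PredictionStream:
    """Centered moving average over frames within ±``window_s``/2.

    The window is defined on timestamps, so the stream is rate-agnostic;
    at the recording boundaries the window simply truncates.  ``window_s``
    of 0 returns an identical copy.
    """
    if window_s < 0:
        raise NegativeDuration(f"window_s={window_s}")
    if len(stream) == 0:
        raise EmptyStream("cannot smooth an empty stream")
    if window_s == 0:
        return stream.with_confidences(stream.confidences.copy())
    ts = stream.timestamps
    half = window_s / 2.0
    lo = np.searchsorted(ts, ts - half, side="left")
    hi = np.searchsorted(ts, ts + half, side="right")
    out = np.empty_like(stream.confidences)
    conf = stream.confidences
    for i in range(len(ts)):
        out[i] = _window_mean(conf, int(lo[i]), int(hi[i]))
    return stream.with_confidences(out)


# ---------------------------------------------------------------------------
# run algebra
# ---------------------------------------------------------------------------

def runs_from_mask(timestamps: np.ndarray, mask: np.ndarray,
                   end_s: float) -> list[Interval]:
    """Maximal True runs as half-open intervals.

    A run starts at the timestamp of its first frame and ends at the
    timestamp of the first frame after it (or ``end_s`` if it reaches the
    end of the stream).
    """
    padded = np.concatenate(([False], np.asarray(mask, dtype=bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    n = len(timestamps)
    return [(float(timestamps[s]),
             float(timestamps[e]) if e < n else float(end_s))
            for s, e in zip(starts, ends)]


def merge_runs(runs: Sequence[Interval], max_gap_s: float) -> list[Interval]:
    """Merge runs whose separating gap is strictly below ``max_gap_s``."""
    merged: list[list[float]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < max_gap_s:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def filter_runs(runs: Sequence[Interval],
                min_duration_s: float) -> list[Interval]:
    """Drop runs shorter than ``min_duration_s``."""
    return [(s, e) for s, e in runs if e - s >= min_duration_s]


def clip_runs(runs: Sequence[Interval], lo: float,
              hi: float) -> list[Interval]:
    """Clip runs to ``[lo, hi)``, dropping those that fall empty."""
    clipped = [(max(s, lo), min(e, hi)) for s, e in runs]
    return [(s, e) for s, e in clipped if s < e]


# --- evidence masks ---------------------------------------------------------

def _in_body_mask(stream: PredictionStream,
                  config: PipelineConfig) -> np.ndarray:
    return stream.label("outside") < config.threshold("outside")


def _any_above(stream: PredictionStream, labels: Sequence[str],
               config: PipelineConfig) -> np.ndarray:
    mask = np.zeros(len(stream), dtype=bool)
    for label in labels:
        mask |= stream.label(label) >= config.threshold(label)
    return mask


def body_runs(stream: PredictionStream,
              config: PipelineConfig) -> list[Interval]:
    return runs_from_mask(stream.timestamps, _in_body_mask(stream, config),
                          stream.end_s)


def cecum_evidence_runs(stream: PredictionStream,
                        config: PipelineConfig) -> list[Interval]:
    return runs_from_mask(stream.timestamps,
                          _any_above(stream, LANDMARK_LABELS, config),
                          stream.end_s)


def intervention_evidence_runs(stream: PredictionStream,
                               config: PipelineConfig) -> list[Interval]:
    return runs_from_mask(
        stream.timestamps,
        _any_above(stream, INTERVENTION_EVIDENCE_LABELS, config),
        stream.end_s)


def polyp_evidence_runs(stream: PredictionStream,
                        config: PipelineConfig) -> list[Interval]:
    return runs_from_mask(stream.timestamps,
                          _any_above(stream, ("polyp",), config),
                          stream.end_s)


# ---------------------------------------------------------------------------
# detection operations (expect a smoothed stream)
# ---------------------------------------------------------------------------

def _body_from_runs(runs: Sequence[Interval],
                    config: PipelineConfig) -> Interval:
    sustained = filter_runs(runs, config.min_sustain_s)
    if not sustained:
        raise NoBodyDetected("no sustained in-body run")
    return sustained[0][0], sustained[-1][1]


def _cecum_from_runs(runs: Sequence[Interval], body: Interval,
                     config: PipelineConfig) -> Interval:
    clipped = clip_runs(runs, body[0], body[1])
    sustained = filter_runs(clipped, config.min_sustain_s)
    if not sustained:
        raise NoCecumDetected("no sustained cecal-landmark evidence run")
    return sustained[0][0], sustained[-1][1]


def _overlays_from_runs(runs: Sequence[Interval], body: Interval,
                        config: PipelineConfig) -> list[Interval]:
    merged = merge_runs(runs, config.merge_gap_s)
    kept = filter_runs(merged, config.min_duration_s)
    return clip_runs(kept, body[0], body[1])


def detect_body_interval(stream: PredictionStream,
                         config: PipelineConfig | None = None) -> Interval:
    """In-body interval from sustained runs of low ``outside`` confidence.

    Returns the half-open interval from the start of the first sustained
    in-body run to the end of the last one.
    """
    config = validate_config(config)
    if len(stream) == 0:
        raise EmptyStream("empty stream")
    return _body_from_runs(body_runs(stream, config), config)


def detect_cecum_anchors(stream: PredictionStream, body: Interval,
                         config: PipelineConfig | None = None) -> Interval:
    """(t_first_cecum, t_last_cecum) from sustained landmark evidence.

    A frame provides cecum evidence when any of the three landmark labels
    (ileum, appendiceal orifice, ileocecal valve) reaches its threshold;
    the anchors span from the start of the first sustained evidence run to
    the end of the last, both within the body interval.

    Raises
    ------
    NoCecumDetected : when no sustained run exists — the pipeline cannot
        report a withdrawal time for such an exam.
    """
    config = validate_config(config)
    return _cecum_from_runs(cecum_evidence_runs(stream, config), body,
                            config)


def detect_interventions(stream: PredictionStream, body: Interval,
                         config: PipelineConfig | None = None,
                         ) -> list[Interval]:
    """Intervention intervals: merged, filtered, body-clipped evidence runs.

    Evidence is any of polyp / biopsy forceps / snare / wound at or above
    its threshold; runs separated by less than ``merge_gap_s`` merge, runs
    shorter than ``min_duration_s`` drop, and the result is clipped (never
    extended) at the body boundaries.  An empty list is a valid outcome.
    """
    config = validate_config(config)
    return _overlays_from_runs(intervention_evidence_runs(stream, config),
                               body, config)


def timeline_from_runs(body: Sequence[Interval],
                       cecum: Sequence[Interval],
                       intervention: Sequence[Interval],
                       polyp: Sequence[Interval],
                       end_s: float,
                       config: PipelineConfig) -> ExamTimeline:
    """Assemble an :class:`ExamTimeline` from raw evidence runs.

    Shared by the offline pipeline and the streaming engine, which obtain
    the same raw runs by different routes.
    """
    body_iv = _body_from_runs(body, config)
    t_first, t_last = _cecum_from_runs(cecum, body_iv, config)
    interventions = _overlays_from_runs(intervention, body_iv, config)
    polyps = _overlays_from_runs(polyp, body_iv, config)
    return ExamTimeline.from_anchors(
        body_iv[0], t_first, t_last, body_iv[1], end_s=end_s,
        interventions=interventions, polyp_sequences=polyps)


def segment_exam(stream: PredictionStream,
                 config: PipelineConfig | None = None) -> ExamTimeline:
    """Full segmentation: smooth, then detect body, cecum, interventions.

    Raises ``NoBodyDetected`` / ``NoCecumDetected`` when the respective
    evidence is absent; no timeline (and hence no timing summary) is
    produced for such exams.
    """
    config = validate_config(config)
    sm = smooth(stream, config.window_s)
    return timeline_from_runs(body_runs(sm, config),
                              cecum_evidence_runs(sm, config),
                              intervention_evidence_runs(sm, config),
                              polyp_evidence_runs(sm, config),
                              sm.end_s, config)
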