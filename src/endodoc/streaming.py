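"""Real-time streaming engine with exact offline equivalence.

The engine ingests frames one at a time (the reference rate is 10 fps, but
the engine is rate-agnostic) and maintains, incrementally:

* a rolling smoothing buffer — a frame is smoothed once a frame more than
  half a window ahead of it has arrived, so the centered moving average is
  identical to the offline one (the induced latency is ``window_s``/2);
* open/closed evidence runs for the four segmentation signals (in-body,
  cecal landmark, intervention, polyp);
* provisional landmark-image trackers and provisional anchors for advisory
  mid-exam display.

``finalize()`` assembles the timeline from the tracked runs, computes the
timing summary and builds the report from the accumulated smoothed frames
using the very same functions as the offline pipeline, so its serialized
output is bit-equal to :func:`endodoc.pipeline.run_pipeline` on the same
frames.  Per-push work is bounded by the smoothing window length (no
full-stream re-scan); the ``max_push_ops`` counter exposes this for
instrumentation.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig, validate_config
from .errors import EmptyStream, OutOfOrderFrame
from .report import ImageReport, build_report
from .segmentation import (
    ExamTimeline,
    _window_mean,
    timeline_from_runs,
)
from .stream import FramePrediction, PredictionStream
from .taxonomy import (
    IMAGE_LABELS,
    INTERVENTION_EVIDENCE_LABELS,
    LABEL_INDEX,
    LANDMARK_LABELS,
    UNINFORMATIVE_LABELS,
)
from .timing import TimingSummary, compute_times

__all__ = ["StreamState", "process_stream"]

_SIGNALS = ("body", "cecum", "intervention", "polyp")


class StreamState:
    """Incremental state of one streamed exam."""

    def __init__(self, fps: float,
                 config: PipelineConfig | None = None,
                 source_id: str = "stream") -> None:
        self.config = validate_config(config)
        self.fps = float(fps)
        self.source_id = source_id
        self._half = self.config.window_s / 2.0

        labels = len(IMAGE_LABELS)
        self._cap = 1024
        self._idx = np.empty(self._cap, dtype=np.int64)
        self._ts = np.empty(self._cap, dtype=np.float64)
        self._conf = np.empty((self._cap, labels), dtype=np.float64)
        self._sm = np.empty((self._cap, labels), dtype=np.float64)
        self._n = 0          # frames pushed
        self._p = 0          # next frame awaiting smoothing
        self._lo = 0         # left edge of the current smoothing window

        cfg = self.config
        self._thr = np.array([cfg.threshold(l) for l in IMAGE_LABELS])
        self._j_outside = LABEL_INDEX["outside"]
        self._j_landmarks = [LABEL_INDEX[l] for l in LANDMARK_LABELS]
        self._j_evidence = [LABEL_INDEX[l]
                            for l in INTERVENTION_EVIDENCE_LABELS]
        self._j_polyp = LABEL_INDEX["polyp"]
        self._j_uninformative = [LABEL_INDEX[l] for l in UNINFORMATIVE_LABELS]

        self._runs: dict[str, list[tuple[float, float]]] = \
            {s: [] for s in _SIGNALS}
        self._open: dict[str, float | None] = {s: None for s in _SIGNALS}

        # advisory per-landmark best eligible frame: label -> (score, index)
        self._landmark_best: dict[str, tuple[float, int] | None] = \
            {l: None for l in LANDMARK_LABELS}

        self.frames_seen = 0
        self.max_push_ops = 0
        self.total_ops = 0

    # --- ingest -------------------------------------------------------------

    def push(self, frame: FramePrediction) -> "StreamState":
        """Ingest one frame; amortized cost bounded by the window length."""
        ops = 1
        if self._n and frame.timestamp_s <= self._ts[self._n - 1]:
            raise OutOfOrderFrame(
                f"timestamp {frame.timestamp_s} <= previous "
                f"{self._ts[self._n - 1]}")
        if self._n == self._cap:
            self._grow()
        i = self._n
        self._idx[i] = frame.frame_index
        self._ts[i] = frame.timestamp_s
        self._conf[i] = frame.as_row()
        self._n += 1
        self.frames_seen += 1
        # smooth every frame whose full centered window is now available
        while self._p < self._n - 1 \
                and self._ts[self._p] + self._half < frame.timestamp_s:
            ops += self._emit(self._p, self._n - 2)
        self.total_ops += ops
        self.max_push_ops = max(self.max_push_ops, ops)
        return self

    def _grow(self) -> None:
        self._cap *= 2
        for name in ("_idx", "_ts", "_conf", "_sm"):
            old = getattr(self, name)
            new = np.empty((self._cap, *old.shape[1:]), dtype=old.dtype)
            new[:self._n] = old[:self._n]
            setattr(self, name, new)

    def _emit(self, p: int, hi: int) -> int:
        """Smooth frame ``p`` (window ends at frame ``hi``) and update
        the run trackers.  Returns an operation count."""
        ops = 1
        t_lo = float(self._ts[p]) - self._half
        while self._ts[self._lo] < t_lo:
            self._lo += 1
            ops += 1
        row = _window_mean(self._conf, self._lo, hi + 1)
        self._sm[p] = row
        ops += hi + 1 - self._lo

        t = float(self._ts[p])
        thr = self._thr
        self._track("body", row[self._j_outside] < thr[self._j_outside], t)
        self._track("cecum",
                    any(row[j] >= thr[j] for j in self._j_landmarks), t)
        self._track("intervention",
                    any(row[j] >= thr[j] for j in self._j_evidence), t)
        self._track("polyp", row[self._j_polyp] >= thr[self._j_polyp], t)

        if all(row[j] < thr[j] for j in self._j_uninformative):
            for label, j in zip(LANDMARK_LABELS, self._j_landmarks):
                score = float(row[j])
                if score >= thr[j]:
                    best = self._landmark_best[label]
                    if best is None or score > best[0]:
                        self._landmark_best[label] = (score, p)
        self._p = p + 1
        return ops

    def _track(self, signal: str, active: bool, t: float) -> None:
        if active and self._open[signal] is None:
            self._open[signal] = t
        elif not active and self._open[signal] is not None:
            self._runs[signal].append((self._open[signal], t))
            self._open[signal] = None

    # --- provisional views --------------------------------------------------

    @property
    def provisional_anchors(self) -> dict[str, float | None]:
        """Advisory mid-exam anchors from the runs seen so far."""
        body = self._closed_runs("body")
        cecum = self._closed_runs("cecum")
        return {
            "t_enter_body": body[0][0] if body else None,
            "t_first_cecum": cecum[0][0] if cecum else None,
            "t_last_cecum": cecum[-1][1] if cecum else None,
        }

    def _closed_runs(self, signal: str,
                     end_s: float | None = None) -> list[tuple[float, float]]:
        runs = list(self._runs[signal])
        if self._open[signal] is not None:
            runs.append((self._open[signal],
                         end_s if end_s is not None
                         else float(self._ts[self._p - 1])))
        return runs

    # --- completion ---------------------------------------------------------

    @property
    def end_s(self) -> float:
        return float(self._ts[self._n - 1]) + 1.0 / self.fps

    def finalize(self) -> tuple[ExamTimeline, TimingSummary, ImageReport]:
        """Flush the buffers and return the exam summary.

        The output is exactly what the offline pipeline returns on the
        concatenation of all pushed frames.  Raises ``EmptyStream``,
        ``NoBodyDetected`` or ``NoCecumDetected`` as the offline pipeline
        would.
        """
        if self._n == 0:
            raise EmptyStream("no frames pushed")
        while self._p < self._n:
            self._emit(self._p, self._n - 1)
        end_s = self.end_s
        runs = {s: self._closed_runs(s, end_s) for s in _SIGNALS}
        smoothed = PredictionStream(self._idx[:self._n].copy(),
                                    self._ts[:self._n].copy(),
                                    self._sm[:self._n].copy(),
                                    fps=self.fps, source_id=self.source_id)
        timeline = timeline_from_runs(runs["body"], runs["cecum"],
                                      runs["intervention"], runs["polyp"],
                                      end_s, self.config)
        timing = compute_times(timeline)
        report = build_report(smoothed, timeline, timing, self.config)
        return timeline, timing, report


def process_stream(stream: PredictionStream,
                   config: PipelineConfig | None = None,
                   ) -> tuple[ExamTimeline, TimingSummary, ImageReport]:
    """Push every frame of ``stream`` through a fresh state and finalize."""
    state = StreamState(fps=stream.fps, config=config,
                        source_id=stream.source_id)
    for frame in stream:
        state.push(frame)
    return state.finalize()
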