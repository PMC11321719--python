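"""Offline end-to-end pipeline: stream → timeline → timing → report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .config import PipelineConfig, validate_config
from .report import ImageReport, build_report
from .segmentation import (
    ExamTimeline,
    body_runs,
    cecum_evidence_runs,
    intervention_evidence_runs,
    polyp_evidence_runs,
    segment_exam,
    smooth,
    timeline_from_runs,
)
from .stream import PredictionStream
from .timing import TimingSummary, compute_times

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline produces for one exam."""

    timeline: ExamTimeline
    timing: TimingSummary
    report: ImageReport
    smoothed: PredictionStream


def run_pipeline(stream: PredictionStream,
                 config: PipelineConfig | None = None,
                 frames_dir: str | Path | None = None,
                 images_out: str | Path | None = None) -> PipelineResult:
    """Segment an exam, compute its durations and assemble the report.

    Smoothing happens once; segmentation and image selection both operate
    on the smoothed stream.  Raises ``NoBodyDetected`` / ``NoCecumDetected``
    when the exam cannot be segmented — no timing summary or report is
    produced in that case.
    """
    config = validate_config(config)
    sm = smooth(stream, config.window_s)
    timeline = timeline_from_runs(body_runs(sm, config),
                                  cecum_evidence_runs(sm, config),
                                  intervention_evidence_runs(sm, config),
                                  polyp_evidence_runs(sm, config),
                                  sm.end_s, config)
    timing = compute_times(timeline)
    report = build_report(sm, timeline, timing, config,
                          frames_dir=frames_dir, images_out=images_out)
    return PipelineResult(timeline=timeline, timing=timing, report=report,
                          smoothed=sm)
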