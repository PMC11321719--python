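"""Automatic photodocumentation: image selection and the structured report.

Selection rules
---------------
A frame is *eligible* when no uninformative label (``low_quality``,
``outside``) reaches its binarization threshold.  For each of the three
cecal landmarks the report carries the eligible frame with the highest
confidence for that label, provided the maximum reaches the label's
threshold.  For each polyp sequence up to three roles are filled:

(i)   ``polyp_white_light`` — highest polyp confidence among eligible frames
      with chromoendoscopy and both resection instruments below threshold;
(ii)  ``polyp_chromo`` — highest polyp confidence among eligible frames with
      chromoendoscopy at/above threshold;
(iii) ``polyp_with_instrument`` — the frame maximizing
      ``min(polyp, max(instruments))`` among eligible frames with an
      instrument at/above threshold, so both the polyp and the instrument
      are confidently visible.

Ties go to the earliest eligible frame, making selection independent of
storage order.  Selection operates on the same smoothed confidences the
segmentation used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig, validate_config
from .errors import FrameSourceMismatch, UnwritablePath
from .segmentation import ExamTimeline
from .stream import PredictionStream
from .taxonomy import (
    INSTRUMENT_LABELS,
    LABEL_INDEX,
    LANDMARK_LABELS,
    UNINFORMATIVE_LABELS,
)
from .timing import TimingSummary

__all__ = [
    "SelectedImage",
    "PolypReport",
    "ImageReport",
    "select_landmark_image",
    "select_polyp_images",
    "build_report",
    "render_timeline",
    "FRAME_FILE_PATTERN",
]

POLYP_ROLES = ("polyp_white_light", "polyp_chromo", "polyp_with_instrument")
ROLES = LANDMARK_LABELS + POLYP_ROLES

#: File naming convention for frame directories (index-padded PNGs).
FRAME_FILE_PATTERN = "frame_{:06d}.png"


@dataclass(frozen=True)
class SelectedImage:
    """One frame chosen for the report, with the score that won selection."""

    role: str
    frame_index: int
    timestamp_s: float
    confidence: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown image role {self.role!r}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("selection confidence outside [0, 1]")

    def to_json_dict(self) -> dict:
        return {"role": self.role,
                "frame_index": self.frame_index,
                "timestamp_s": round(self.timestamp_s, 3),
                "confidence": round(self.confidence, 6)}


@dataclass(frozen=True)
class PolypReport:
    """Selected images for one polyp sequence."""

    interval: tuple[float, float]
    images: tuple[SelectedImage, ...]

    def to_json_dict(self) -> dict:
        return {"interval": [round(self.interval[0], 3),
                             round(self.interval[1], 3)],
                "images": [im.to_json_dict() for im in self.images]}


@dataclass(frozen=True)
class ImageReport:
    """The structured exam summary: images, timing and timeline."""

    source_id: str
    timing: TimingSummary
    timeline: ExamTimeline
    landmark_images: tuple[SelectedImage, ...]
    polyp_reports: tuple[PolypReport, ...]

    @property
    def cecum_documented(self) -> bool:
        return len(self.landmark_images) > 0

    def to_json_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "timing": self.timing.to_json_dict(),
            "anchors": self.timeline.to_json_dict()["anchors"],
            "landmarks": [im.to_json_dict() for im in self.landmark_images],
            "polyps": [p.to_json_dict() for p in self.polyp_reports],
            "cecum_documented": self.cecum_documented,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _eligible_mask(stream: PredictionStream,
                   config: PipelineConfig) -> np.ndarray:
    """Frames with no uninformative label at/above its threshold."""
    mask = np.ones(len(stream), dtype=bool)
    for label in UNINFORMATIVE_LABELS:
        mask &= stream.label(label) < config.threshold(label)
    return mask


def _argmax_selection(stream: PredictionStream, scores: np.ndarray,
                      mask: np.ndarray, role: str,
                      require: float | None = None,
                      ) -> SelectedImage | None:
    """Earliest frame maximizing ``scores`` among ``mask`` frames.

    ``require``: minimum winning score; below it, no image is selected.
    """
    if not mask.any():
        return None
    masked = np.where(mask, scores, -1.0)
    i = int(np.argmax(masked))  # argmax returns the first (earliest) maximum
    best = float(masked[i])
    if best < 0 or (require is not None and best < require):
        return None
    return SelectedImage(role=role,
                         frame_index=int(stream.frame_index[i]),
                         timestamp_s=float(stream.timestamps[i]),
                         confidence=best)


def select_landmark_image(stream: PredictionStream, label: str,
                          config: PipelineConfig | None = None,
                          ) -> SelectedImage | None:
    """Best eligible frame for one cecal landmark, or ``None``.

    Searches the whole stream: landmarks are often best seen on withdrawal
    re-inspection, and the eligibility filter already excludes frames
    predicted as outside the body.
    """
    config = validate_config(config)
    if label not in LANDMARK_LABELS:
        raise ValueError(f"{label!r} is not a landmark label")
    return _argmax_selection(stream, stream.label(label),
                             _eligible_mask(stream, config), role=label,
                             require=config.threshold(label))


def select_polyp_images(stream: PredictionStream,
                        sequence: tuple[float, float],
                        config: PipelineConfig | None = None,
                        ) -> list[SelectedImage]:
    """Up to three representative images for one polyp sequence.

    Roles are filled independently and omitted when no qualifying frame
    exists; see the module docstring for the role definitions.
    """
    config = validate_config(config)
    ts = stream.timestamps
    lo = int(np.searchsorted(ts, sequence[0], side="left"))
    hi = int(np.searchsorted(ts, sequence[1], side="left"))
    window = np.zeros(len(stream), dtype=bool)
    window[lo:hi] = True
    eligible = _eligible_mask(stream, config) & window

    polyp = stream.label("polyp")
    chromo_above = stream.label("chromoendoscopy") \
        >= config.threshold("chromoendoscopy")
    instr_conf = np.maximum.reduce(
        [stream.label(l) for l in INSTRUMENT_LABELS])
    instr_above = np.zeros(len(stream), dtype=bool)
    for l in INSTRUMENT_LABELS:
        instr_above |= stream.label(l) >= config.threshold(l)

    images = []
    white = _argmax_selection(
        stream, polyp, eligible & ~chromo_above & ~instr_above,
        role="polyp_white_light")
    if white:
        images.append(white)
    chromo = _argmax_selection(stream, polyp, eligible & chromo_above,
                               role="polyp_chromo")
    if chromo:
        images.append(chromo)
    with_instr = _argmax_selection(
        stream, np.minimum(polyp, instr_conf), eligible & instr_above,
        role="polyp_with_instrument")
    if with_instr:
        images.append(with_instr)
    return images


# ---------------------------------------------------------------------------
# report assembly and export
# ---------------------------------------------------------------------------

def build_report(stream: PredictionStream, timeline: ExamTimeline,
                 timing: TimingSummary,
                 config: PipelineConfig | None = None,
                 frames_dir: str | Path | None = None,
                 images_out: str | Path | None = None) -> ImageReport:
    """Assemble the structured report from one exam's segmented stream.

    ``stream`` should be the smoothed stream the segmentation operated on.
    When ``frames_dir`` is given (PNG frames named ``frame_{index:06d}.png``)
    each selected image is exported to ``images_out`` as
    ``{role}_{frame_index}.png``.
    """
    config = validate_config(config)
    landmarks = tuple(
        im for label in LANDMARK_LABELS
        if (im := select_landmark_image(stream, label, config)) is not None)
    polyps = tuple(
        PolypReport(interval=seq,
                    images=tuple(select_polyp_images(stream, seq, config)))
        for seq in timeline.polyp_sequences)
    report = ImageReport(source_id=stream.source_id, timing=timing,
                         timeline=timeline, landmark_images=landmarks,
                         polyp_reports=polyps)
    if frames_dir is not None:
        if images_out is None:
            raise ValueError("images_out is required when frames_dir is set")
        export_report_images(report, frames_dir, images_out)
    return report


def export_report_images(report: ImageReport, frames_dir: str | Path,
                         out_dir: str | Path) -> list[Path]:
    """Export each selected frame as ``{role}_{frame_index}.png``."""
    from PIL import Image

    frames_dir = Path(frames_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = list(report.landmark_images)
    for polyp in report.polyp_reports:
        selected.extend(polyp.images)
    written = []
    for image in selected:
        src = frames_dir / FRAME_FILE_PATTERN.format(image.frame_index)
        if not src.exists():
            raise FrameSourceMismatch(
                f"no frame file for index {image.frame_index} in "
                f"{frames_dir}")
        dst = out_dir / f"{image.role}_{image.frame_index}.png"
        Image.open(src).save(dst)
        written.append(dst)
    return written


_PHASE_COLORS = {"insertion": "tab:orange", "cecum": "tab:red",
                 "withdrawal": "tab:green", "outside": "0.85"}


def render_timeline(timeline: ExamTimeline, path: str | Path) -> Path:
    """Write the color-coded exam timeline as a PNG.

    Bottom bar: insertion (orange), cecum inspection (red) and withdrawal
    (green), labelled with their durations in minutes.  Overlay bars above:
    polyp sequences (red) and intervention/instrument intervals (yellow).
    Renderer settings are fixed so identical timelines render to identical
    bytes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(10, 2.2), dpi=100)
    for seg in timeline.base_segments:
        ax.broken_barh([(seg.start_s, seg.duration_s)], (0, 0.8),
                       facecolors=_PHASE_COLORS[seg.phase])
        if seg.phase != "outside":
            ax.text(seg.start_s + seg.duration_s / 2, 0.4,
                    f"{seg.duration_s / 60:.1f} min", ha="center",
                    va="center", fontsize=8)
    for start, end in timeline.polyp_sequences:
        ax.broken_barh([(start, end - start)], (1.0, 0.5),
                       facecolors="tab:red")
    for start, end in timeline.interventions:
        ax.broken_barh([(start, end - start)], (1.7, 0.5),
                       facecolors="gold")
    ax.set_ylim(-0.2, 2.5)
    ax.set_xlim(0, timeline.end_s)
    ax.set_yticks([0.4, 1.25, 1.95])
    ax.set_yticklabels(["phase", "polyp", "intervention"], fontsize=8)
    ax.set_xlabel("time [s]")
    fig.tight_layout()
    try:
        fig.savefig(path, metadata={"Software": None})
    except OSError as exc:
        raise UnwritablePath(str(path)) from exc
    finally:
        plt.close(fig)
    return path
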