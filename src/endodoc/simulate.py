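"""Synthetic colonoscopy exams: ground-truth timelines and noisy streams.

A :class:`SyntheticExamSpec` describes an exam as phase durations
(outside → insertion → cecum inspection → withdrawal → outside), polyp
events with optional resection/chromoendoscopy, and landmark visibility
windows inside the cecum phase.  :func:`simulate_exam` turns the spec into
the exact ground-truth :class:`ExamTimeline` and a matching
:class:`PredictionStream` in which each label's confidence is drawn from a
Beta distribution: Beta(8, 2) (mean 0.8) while the label is truly active and
Beta(2, 8) (mean 0.2) while inactive.  These defaults are separable at a 0.5
threshold but overlap enough to exercise smoothing and run filtering; with
``noise=None`` confidences are the exact 1/0 activity pattern.

What the simulator emulates: the temporal phase structure of an exam, the
co-occurrence of polyp/instrument/chromoendoscopy labels during
interventions, a fixed 10 s post-polypectomy wound-care tail, sporadic
low-quality frames (2 % of frames by default), and the ileocecal valve
being in view throughout cecum inspection (it delimits the phase) with the
appendiceal orifice and terminal ileum visible in sub-windows.  It does not
emulate photorealistic appearance, camera motion, or the temporal
confidence autocorrelation of a real CNN (an optional AR(1) blend is
available but off by default).

:func:`render_toy_frames` and :func:`toy_classifier` close the loop for
image-export tests: frames encode active labels as colored glyphs and the
toy classifier recovers them by color masking, standing in for any
image → confidence-map callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidSpec, UnreadableImage, UnwritablePath
from .segmentation import ExamTimeline, merge_runs
from .stream import PredictionStream
from .taxonomy import IMAGE_LABELS, LABEL_INDEX

__all__ = [
    "PolypEvent",
    "NoiseModel",
    "SyntheticExamSpec",
    "simulate_exam",
    "default_exam_spec",
    "random_exam_spec",
    "render_toy_frames",
    "toy_classifier",
    "classify_frame_dir",
    "GLYPH_COLORS",
]

Interval = tuple[float, float]

#: Post-polypectomy wound care tail appended to each resected event [s].
WOUND_TAIL_S = 10.0


@dataclass(frozen=True)
class PolypEvent:
    """One polyp inspection (and optional resection) interval."""

    start_s: float
    duration_s: float
    resected: bool = False
    instrument: str = "snare"
    chromo_used: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidSpec("polyp event duration must be > 0")
        if self.instrument not in ("snare", "biopsy_forceps"):
            raise InvalidSpec(f"unknown instrument {self.instrument!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class NoiseModel:
    """Beta confidence noise: active ~ Beta(a_true, b_true), inactive
    ~ Beta(a_false, b_false); plus sporadic low-quality frames and an
    optional AR(1) temporal blend (0 disables it)."""

    a_true: float = 8.0
    b_true: float = 2.0
    a_false: float = 2.0
    b_false: float = 8.0
    low_quality_rate: float = 0.02
    ar_coeff: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a_true, self.b_true, self.a_false, self.b_false) <= 0:
            raise InvalidSpec("Beta parameters must be > 0")
        if not (0.0 <= self.low_quality_rate < 1.0):
            raise InvalidSpec("low_quality_rate must be in [0, 1)")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise InvalidSpec("ar_coeff must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticExamSpec:
    """Ground truth plus noise model for one synthetic exam.

    ``durations`` are the (outside_pre, insertion, cecum, withdrawal,
    outside_post) phase lengths in seconds.  ``landmark_windows`` maps a
    landmark label to visibility intervals inside the cecum phase; when
    ``None``, the ileocecal valve spans the whole cecum phase and the other
    two landmarks occupy sub-windows.  ``noise=None`` produces exact 1/0
    confidences.
    """

    fps: float = 10.0
    durations: tuple[float, float, float, float, float] = \
        (10.0, 300.0, 60.0, 480.0, 10.0)
    polyp_events: tuple[PolypEvent, ...] = ()
    landmark_windows: Mapping[str, Sequence[Interval]] | None = None
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    seed: int = 0
    source_id: str = "synthetic"

    # --- derived anchors ---------------------------------------------------

    @property
    def t_enter_body(self) -> float:
        return self.durations[0]

    @property
    def t_first_cecum(self) -> float:
        return self.durations[0] + self.durations[1]

    @property
    def t_last_cecum(self) -> float:
        return self.t_first_cecum + self.durations[2]

    @property
    def t_exit_body(self) -> float:
        return self.t_last_cecum + self.durations[3]

    @property
    def total_s(self) -> float:
        return self.t_exit_body + self.durations[4]

    def validate(self) -> None:
        if self.fps <= 0:
            raise InvalidSpec("fps must be > 0")
        if any(d <= 0 for d in self.durations):
            raise InvalidSpec("all phase durations must be > 0")
        for event in self.polyp_events:
            if event.start_s < self.t_enter_body \
                    or event.end_s > self.t_exit_body:
                raise InvalidSpec(
                    f"polyp event ({event.start_s}, {event.end_s}) outside "
                    "the in-body interval")
        for label, windows in (self.landmark_windows or {}).items():
            for start, end in windows:
                if start < self.t_first_cecum or end > self.t_last_cecum:
                    raise InvalidSpec(
                        f"landmark window for {label} outside cecum phase")


# ---------------------------------------------------------------------------
# ground-truth activity
# ---------------------------------------------------------------------------

def _default_landmark_windows(spec: SyntheticExamSpec,
                              ) -> dict[str, list[Interval]]:
    t0, t1 = spec.t_first_cecum, spec.t_last_cecum
    span = t1 - t0
    return {
        # the valve delimits cecum inspection: in view for the whole phase
        "ileocecal_valve": [(t0, t1)],
        "appendix": [(t0 + 0.1 * span, t0 + 0.5 * span)],
        "ileum": [(t0 + 0.5 * span, t0 + 0.8 * span)],
    }


def activity_intervals(spec: SyntheticExamSpec) -> dict[str, list[Interval]]:
    """Per-label ground-truth activity intervals (half-open, seconds).

    During a polyp event the polyp label is active throughout; if
    chromoendoscopy is used it covers the middle third of the event; for a
    resected polyp the instrument covers the final third and the wound label
    a fixed tail after the event (clipped at body exit).
    """
    spec.validate()
    activity: dict[str, list[Interval]] = {l: [] for l in IMAGE_LABELS}
    activity["outside"] = [(0.0, spec.t_enter_body),
                           (spec.t_exit_body, spec.total_s)]
    windows = (dict(spec.landmark_windows) if spec.landmark_windows
               is not None else _default_landmark_windows(spec))
    for label, ivs in windows.items():
        activity[label] = [tuple(iv) for iv in ivs]
    for ev in spec.polyp_events:
        activity["polyp"].append((ev.start_s, ev.end_s))
        third = ev.duration_s / 3.0
        if ev.chromo_used:
            activity["chromoendoscopy"].append(
                (ev.start_s + third, ev.start_s + 2 * third))
        if ev.resected:
            activity[ev.instrument].append((ev.end_s - third, ev.end_s))
            wound_end = min(ev.end_s + WOUND_TAIL_S, spec.t_exit_body)
            if wound_end > ev.end_s:
                activity["wound"].append((ev.end_s, wound_end))
    return activity


def ground_truth_timeline(spec: SyntheticExamSpec) -> ExamTimeline:
    """The exact timeline implied by the spec (no noise, no detection)."""
    activity = activity_intervals(spec)
    evidence = sorted(activity["polyp"] + activity["biopsy_forceps"]
                      + activity["snare"] + activity["wound"])
    interventions = merge_runs(evidence, 0.0)  # union of touching intervals
    polyps = merge_runs(sorted(activity["polyp"]), 0.0)
    n = int(round(spec.total_s * spec.fps))
    return ExamTimeline.from_anchors(
        spec.t_enter_body, spec.t_first_cecum, spec.t_last_cecum,
        spec.t_exit_body, end_s=n / spec.fps,
        interventions=interventions, polyp_sequences=polyps)


def _activity_matrix(spec: SyntheticExamSpec,
                     timestamps: np.ndarray) -> np.ndarray:
    active = np.zeros((len(timestamps), len(IMAGE_LABELS)), dtype=bool)
    for label, intervals in activity_intervals(spec).items():
        j = LABEL_INDEX[label]
        for start, end in intervals:
            lo = int(np.searchsorted(timestamps, start, side="left"))
            hi = int(np.searchsorted(timestamps, end, side="left"))
            active[lo:hi, j] = True
    return active


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_exam(spec: SyntheticExamSpec,
                  ) -> tuple[ExamTimeline, PredictionStream]:
    """Ground-truth timeline plus a (noisy) prediction stream.

    Deterministic given ``spec.seed``: the same spec always yields the
    identical stream.
    """
    spec.validate()
    n = int(round(spec.total_s * spec.fps))
    if n == 0:
        raise InvalidSpec("spec describes a zero-frame exam")
    timestamps = np.arange(n, dtype=np.float64) / spec.fps
    active = _activity_matrix(spec, timestamps)
    if spec.noise is None:
        conf = active.astype(np.float64)
    else:
        noise = spec.noise
        rng = np.random.default_rng(spec.seed)
        if noise.low_quality_rate > 0:
            lq = rng.random(n) < noise.low_quality_rate
            active[:, LABEL_INDEX["low_quality"]] |= lq
        true_draw = rng.beta(noise.a_true, noise.b_true, size=active.shape)
        false_draw = rng.beta(noise.a_false, noise.b_false,
                              size=active.shape)
        conf = np.where(active, true_draw, false_draw)
        if noise.ar_coeff > 0:
            rho = noise.ar_coeff
            for i in range(1, n):
                conf[i] = rho * conf[i - 1] + (1.0 - rho) * conf[i]
    stream = PredictionStream(np.arange(n, dtype=np.int64), timestamps,
                              conf, fps=spec.fps, source_id=spec.source_id)
    return ground_truth_timeline(spec), stream


def default_exam_spec(seed: int = 0,
                      noise: NoiseModel | None = NoiseModel(),
                      ) -> SyntheticExamSpec:
    """A representative exam: 5 min insertion, 1 min cecum inspection,
    8 min withdrawal with two polyp sequences (one snare resection under
    chromoendoscopy, one plain inspection)."""
    spec = SyntheticExamSpec(seed=seed, noise=noise)
    t_wd = spec.t_last_cecum
    return replace(spec, polyp_events=(
        PolypEvent(start_s=t_wd + 60.0, duration_s=45.0, resected=True,
                   instrument="snare", chromo_used=True),
        PolypEvent(start_s=t_wd + 300.0, duration_s=20.0, resected=False),
    ))


def random_exam_spec(seed: int,
                     noise: NoiseModel | None = NoiseModel(),
                     ) -> SyntheticExamSpec:
    """Randomized but realistic exam structure, deterministic in ``seed``.

    Phase durations: outside 5–15 s, insertion 2–5 min, cecum inspection
    30–90 s, withdrawal 4–9 min.  Zero to three polyp events (15–60 s,
    70 % resected, mostly by snare, chromoendoscopy half the time) spaced
    at least 20 s apart within withdrawal.  All times are multiples of one
    frame period.
    """
    rng = np.random.default_rng(seed)

    def r(lo: float, hi: float) -> float:
        return round(float(rng.uniform(lo, hi)), 1)

    durations = (r(5, 15), r(120, 300), r(30, 90), r(240, 540), r(5, 15))
    spec = SyntheticExamSpec(durations=durations, seed=seed, noise=noise,
                             source_id=f"synthetic-{seed}")
    n_events = int(rng.integers(0, 4))
    events = []
    cursor = spec.t_last_cecum + r(20, 60)
    for _ in range(n_events):
        duration = r(15, 60)
        if cursor + duration + WOUND_TAIL_S + 20 > spec.t_exit_body:
            break
        resected = bool(rng.random() < 0.7)
        events.append(PolypEvent(
            start_s=round(cursor, 1), duration_s=duration,
            resected=resected,
            instrument="snare" if rng.random() < 0.75 else "biopsy_forceps",
            chromo_used=bool(rng.random() < 0.5)))
        cursor += duration + WOUND_TAIL_S + r(20, 90)
    return replace(spec, polyp_events=tuple(events))


# ---------------------------------------------------------------------------
# toy frames and classifier
# ---------------------------------------------------------------------------

#: Label → glyph RGB color; chosen mutually distant so color masking is
#: unambiguous.
GLYPH_COLORS: dict[str, tuple[int, int, int]] = {
    "ileum": (230, 30, 30),
    "appendix": (30, 200, 30),
    "ileocecal_valve": (40, 70, 240),
    "polyp": (240, 220, 30),
    "chromoendoscopy": (40, 220, 220),
    "biopsy_forceps": (230, 40, 230),
    "snare": (240, 140, 20),
    "wound": (140, 70, 20),
    "low_quality": (150, 150, 150),
    "outside": (250, 250, 250),
}

_BG = (25, 25, 25)
_GLYPH = 8  # glyph square side in px
_COLS = 5


def _glyph_box(j: int) -> tuple[int, int]:
    """Top-left pixel of label j's glyph on the 5 × 2 grid."""
    row, col = divmod(j, _COLS)
    return 4 + col * (_GLYPH + 4), 4 + row * (_GLYPH + 4)


def render_toy_frames(spec: SyntheticExamSpec,
                      out_dir: str | Path) -> Path:
    """Write one small PNG per frame, encoding active labels as glyphs.

    Legend: each label owns a fixed grid position and color
    (:data:`GLYPH_COLORS`); a frame shows an 8 px square per active label
    on a dark background.  Files are named ``frame_{index:06d}.png``.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise UnwritablePath(str(out_dir)) from exc
    n = int(round(spec.total_s * spec.fps))
    timestamps = np.arange(n, dtype=np.float64) / spec.fps
    active = _activity_matrix(spec, timestamps)
    width = 4 + _COLS * (_GLYPH + 4)
    height = 4 + 2 * (_GLYPH + 4)
    for i in range(n):
        arr = np.empty((height, width, 3), dtype=np.uint8)
        arr[:] = _BG
        for j, label in enumerate(IMAGE_LABELS):
            if active[i, j]:
                x, y = _glyph_box(j)
                arr[y:y + _GLYPH, x:x + _GLYPH] = GLYPH_COLORS[label]
        Image.fromarray(arr).save(out_dir / f"frame_{i:06d}.png")
    return out_dir


def toy_classifier(image) -> dict[str, float]:
    """Recover label confidences from a toy frame by color masking.

    Accepts a path or a PIL image.  Returns 0.95 for labels whose glyph is
    present and 0.05 otherwise — a deliberately confident but imperfect
    stand-in for a trained CNN, exercising the 0.5 binarization exactly as
    real confidences would.
    """
    from PIL import Image, UnidentifiedImageError

    if isinstance(image, (str, Path)):
        try:
            image = Image.open(image)
        except (OSError, UnidentifiedImageError) as exc:
            raise UnreadableImage(str(image)) from exc
    arr = np.asarray(image.convert("RGB"), dtype=np.int16)
    conf = {}
    for j, label in enumerate(IMAGE_LABELS):
        x, y = _glyph_box(j)
        block = arr[y:y + _GLYPH, x:x + _GLYPH]
        color = np.array(GLYPH_COLORS[label], dtype=np.int16)
        present = bool(np.abs(block.mean(axis=(0, 1)) - color).max() < 30)
        conf[label] = 0.95 if present else 0.05
    return conf


def classify_frame_dir(frames_dir: str | Path, fps: float,
                       source_id: str = "") -> PredictionStream:
    """Run :func:`toy_classifier` over an index-named frame directory."""
    from .stream import FramePrediction

    frames_dir = Path(frames_dir)
    files = sorted(frames_dir.glob("frame_*.png"))
    frames = []
    for path in files:
        index = int(path.stem.split("_")[1])
        frames.append(FramePrediction(
            frame_index=index, timestamp_s=index / fps,
            confidences=toy_classifier(path)))
    return PredictionStream.from_frames(
        frames, fps=fps, source_id=source_id or frames_dir.name)
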