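"""Prediction-stream data model and readers/writers.

A :class:`PredictionStream` holds one multilabel confidence vector per video
frame.  Confidences are independent per label (multilabel classification:
they need not sum to one).  Timestamps are seconds from recording start and
must be strictly increasing; for streams derived from video they equal
``frame_index / fps``.

On disk a stream is a CSV with the fixed column order
``frame_index, timestamp_s, <the 10 image labels in taxonomy order>``
and confidences serialized with six decimals, or alternatively a JSONL file
with one ``{"frame_index", "timestamp_s", "confidences"}`` object per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfidenceOutOfRange,
    MissingLabelColumn,
    NonMonotoneTimestamps,
    UnwritablePath,
)
from .taxonomy import IMAGE_LABELS, LABEL_INDEX

__all__ = ["FramePrediction", "PredictionStream",
           "read_prediction_stream", "write_prediction_stream"]


@dataclass(frozen=True)
class FramePrediction:
    """One frame's timestamp and per-label confidences."""

    frame_index: int
    timestamp_s: float
    confidences: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.timestamp_s < 0:
            raise ValueError("timestamp_s must be >= 0")
        missing = [l for l in IMAGE_LABELS if l not in self.confidences]
        if missing:
            raise MissingLabelColumn(f"missing confidences for {missing}")
        for label in IMAGE_LABELS:
            c = self.confidences[label]
            if not (0.0 <= c <= 1.0):
                raise ConfidenceOutOfRange(
                    f"{label}={c!r} at frame {self.frame_index}")

    def as_row(self) -> np.ndarray:
        """Confidences as a float vector in taxonomy label order."""
        return np.array([self.confidences[l] for l in IMAGE_LABELS],
                        dtype=np.float64)


class PredictionStream:
    """An ordered sequence of frame predictions backed by numpy arrays.

    Parameters
    ----------
    frame_index : (n,) int array of frame indices.
    timestamps : (n,) float array of strictly increasing timestamps [s].
    confidences : (n, 10) float array, columns in taxonomy label order.
    fps : frames per second of the source (used only for end-of-stream
        bookkeeping; the stream itself is rate-agnostic).
    source_id : free-text identifier of the exam/video.
    """

    def __init__(self,
                 frame_index: np.ndarray,
                 timestamps: np.ndarray,
                 confidences: np.ndarray,
                 fps: float,
                 source_id: str = "",
                 validate: bool = True) -> None:
        self.frame_index = np.asarray(frame_index, dtype=np.int64)
        self.timestamps = np.asarray(timestamps, dtype=np.float64)
        self.confidences = np.ascontiguousarray(confidences, dtype=np.float64)
        self.fps = float(fps)
        self.source_id = source_id
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.timestamps)
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.confidences.shape != (n, len(IMAGE_LABELS)):
            raise MissingLabelColumn(
                f"confidence matrix has shape {self.confidences.shape}, "
                f"expected ({n}, {len(IMAGE_LABELS)})")
        if len(self.frame_index) != n:
            raise ValueError("frame_index and timestamps length mismatch")
        if n and np.any(np.diff(self.timestamps) <= 0):
            raise NonMonotoneTimestamps(
                "timestamps must be strictly increasing")
        if n and (self.confidences.min() < 0.0
                  or self.confidences.max() > 1.0):
            raise ConfidenceOutOfRange("confidences must lie in [0, 1]")

    # --- constructors -------------------------------------------------------

    @classmethod
    def from_frames(cls, frames: Sequence[FramePrediction], fps: float,
                    source_id: str = "") -> "PredictionStream":
        idx = np.array([f.frame_index for f in frames], dtype=np.int64)
        ts = np.array([f.timestamp_s for f in frames], dtype=np.float64)
        if frames:
            conf = np.stack([f.as_row() for f in frames])
        else:
            conf = np.empty((0, len(IMAGE_LABELS)))
        return cls(idx, ts, conf, fps=fps, source_id=source_id)

    # --- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> FramePrediction:
        return FramePrediction(
            frame_index=int(self.frame_index[i]),
            timestamp_s=float(self.timestamps[i]),
            confidences={l: float(self.confidences[i, j])
                         for j, l in enumerate(IMAGE_LABELS)},
        )

    def __iter__(self) -> Iterator[FramePrediction]:
        return (self.frame(i) for i in range(len(self)))

    def label(self, name: str) -> np.ndarray:
        """Confidence column for one label (a view, do not mutate)."""
        return self.confidences[:, LABEL_INDEX[name]]

    @property
    def end_s(self) -> float:
        """End of the stream interval: last timestamp plus one frame period."""
        if not len(self):
            return 0.0
        return float(self.timestamps[-1]) + 1.0 / self.fps

    def with_confidences(self, confidences: np.ndarray) -> "PredictionStream":
        """Copy of this stream with a replaced confidence matrix."""
        return PredictionStream(self.frame_index.copy(),
                                self.timestamps.copy(),
                                confidences, fps=self.fps,
                                source_id=self.source_id)


def read_prediction_stream(path: str | Path, fps: float) -> PredictionStream:
    """Read a prediction stream from CSV (or JSONL, by ``.jsonl`` suffix).

    Raises
    ------
    MissingLabelColumn, NonMonotoneTimestamps, ConfidenceOutOfRange
    """
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        return _read_jsonl(path, fps)
    df = pd.read_csv(path)
    required = ["frame_index", "timestamp_s", *IMAGE_LABELS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingLabelColumn(f"{path}: missing columns {missing}")
    conf = df[list(IMAGE_LABELS)].to_numpy(dtype=np.float64)
    return PredictionStream(df["frame_index"].to_numpy(dtype=np.int64),
                            df["timestamp_s"].to_numpy(dtype=np.float64),
                            conf, fps=fps, source_id=path.stem)


def _read_jsonl(path: Path, fps: float) -> PredictionStream:
    frames = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            frames.append(FramePrediction(
                frame_index=int(obj["frame_index"]),
                timestamp_s=float(obj["timestamp_s"]),
                confidences=obj["confidences"]))
    stream = PredictionStream.from_frames(frames, fps=fps,
                                          source_id=path.stem)
    return stream


def write_prediction_stream(stream: PredictionStream,
                            path: str | Path) -> Path:
    """Write a stream as CSV (or JSONL, by suffix); returns the path.

    Column order is fixed (``frame_index, timestamp_s`` then the taxonomy
    labels); floats are serialized with six decimals, below any clinically
    meaningful confidence resolution.
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".jsonl":
            with open(path, "w") as fh:
                for f in stream:
                    fh.write(json.dumps({
                        "frame_index": f.frame_index,
                        "timestamp_s": round(f.timestamp_s, 6),
                        "confidences": {l: round(f.confidences[l], 6)
                                        for l in IMAGE_LABELS}}) + "\n")
            return path
        df = pd.DataFrame({"frame_index": stream.frame_index,
                           "timestamp_s": stream.timestamps})
        for j, label in enumerate(IMAGE_LABELS):
            df[label] = stream.confidences[:, j] if len(stream) else []
        df.to_csv(path, index=False, float_format="%.6f")
        return path
    except OSError as exc:
        raise UnwritablePath(str(path)) from exc
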