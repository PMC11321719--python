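"""Pipeline configuration: binarization thresholds and temporal windows.

Defaults follow the reference operating point of the pipeline: a 0.5
binarization threshold per label, a 1 s centered smoothing window, a 2 s
minimum sustain for body/landmark evidence runs (rejecting single-frame
false positives at 10 fps), a 5 s merge gap and 2 s minimum duration for
intervention intervals, and a 20 % relative-divergence flag for
withdrawal-time comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import InvalidThreshold, NegativeDuration
from .taxonomy import IMAGE_LABELS

__all__ = ["PipelineConfig", "validate_config", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.5

_DURATION_FIELDS = ("window_s", "min_sustain_s", "merge_gap_s",
                    "min_duration_s")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and windows steering segmentation and image selection.

    Attributes
    ----------
    thresholds : per-label binarization thresholds in (0, 1); labels not
        listed fall back to 0.5 when validated.
    window_s : width of the centered moving-average smoothing window [s].
    min_sustain_s : minimum duration of a body/landmark evidence run [s].
    merge_gap_s : intervention runs closer than this are merged [s].
    min_duration_s : merged intervention runs shorter than this drop [s].
    divergence_threshold : relative withdrawal-time divergence above which
        an exam is flagged (strictly greater than).
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    window_s: float = 1.0
    min_sustain_s: float = 2.0
    merge_gap_s: float = 5.0
    min_duration_s: float = 2.0
    divergence_threshold: float = 0.20

    def threshold(self, label: str) -> float:
        return self.thresholds.get(label, DEFAULT_THRESHOLD)

    # --- file round trip ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return validate_config(cls(**data))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {"thresholds": dict(self.thresholds),
                "window_s": self.window_s,
                "min_sustain_s": self.min_sustain_s,
                "merge_gap_s": self.merge_gap_s,
                "min_duration_s": self.min_duration_s,
                "divergence_threshold": self.divergence_threshold}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path


def validate_config(config: PipelineConfig | None = None) -> PipelineConfig:
    """Return a validated config with per-label threshold defaults filled.

    Raises
    ------
    InvalidThreshold : a threshold (or the divergence fraction) is outside
        (0, 1), or names an unknown label.
    NegativeDuration : a window/duration parameter is negative.
    """
    if config is None:
        config = PipelineConfig()
    unknown = [l for l in config.thresholds if l not in IMAGE_LABELS]
    if unknown:
        raise InvalidThreshold(f"thresholds for unknown labels: {unknown}")
    thresholds = {l: float(config.thresholds.get(l, DEFAULT_THRESHOLD))
                  for l in IMAGE_LABELS}
    for label, t in thresholds.items():
        if not (0.0 < t < 1.0):
            raise InvalidThreshold(f"threshold {label}={t} outside (0, 1)")
    if not (0.0 < config.divergence_threshold < 1.0):
        raise InvalidThreshold(
            f"divergence_threshold={config.divergence_threshold} "
            "outside (0, 1)")
    for name in _DURATION_FIELDS:
        value = getattr(config, name)
        if value < 0:
            raise NegativeDuration(f"{name}={value} must be >= 0")
    return replace(config, thresholds=thresholds)
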