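"""Label taxonomy for colonoscopy frame classification.

The image-level labels cover the three cecal landmarks (terminal ileum,
appendiceal orifice — canonically named ``appendix`` — and ileocecal valve),
intervention-related content (polyp, virtual chromoendoscopy, biopsy forceps,
snare, post-polypectomy wound) and uninformative frames (low quality, outside
the body).  Phase labels describe the exam-level segmentation an annotator
would produce: outside → insertion → cecum inspection → withdrawal, with
intervention intervals overlaid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "IMAGE_LABELS",
    "PHASE_LABELS",
    "LANDMARK_LABELS",
    "UNINFORMATIVE_LABELS",
    "INSTRUMENT_LABELS",
    "INTERVENTION_EVIDENCE_LABELS",
    "LABEL_INDEX",
    "LabelTaxonomy",
    "TAXONOMY",
]

IMAGE_LABELS: tuple[str, ...] = (
    "ileum",
    "appendix",
    "ileocecal_valve",
    "polyp",
    "chromoendoscopy",
    "biopsy_forceps",
    "snare",
    "wound",
    "low_quality",
    "outside",
)

PHASE_LABELS: tuple[str, ...] = (
    "outside",
    "insertion",
    "cecum",
    "withdrawal",
    "intervention",
)

LANDMARK_LABELS: tuple[str, ...] = ("ileum", "appendix", "ileocecal_valve")
UNINFORMATIVE_LABELS: tuple[str, ...] = ("low_quality", "outside")
INSTRUMENT_LABELS: tuple[str, ...] = ("biopsy_forceps", "snare")

# Evidence that an endoscopic intervention (inspection, cleaning, resection,
# wound care) is under way.  Chromoendoscopy is deliberately excluded: digital
# image enhancement is also used during plain mucosal inspection.
INTERVENTION_EVIDENCE_LABELS: tuple[str, ...] = (
    "polyp",
    "biopsy_forceps",
    "snare",
    "wound",
)

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(IMAGE_LABELS)}


@dataclass(frozen=True)
class LabelTaxonomy:
    """The fixed 10-label image taxonomy plus exam-phase labels.

    Frozen so a taxonomy instance can be shared freely; invariants are
    checked at construction.
    """

    image_labels: tuple[str, ...] = IMAGE_LABELS
    phase_labels: tuple[str, ...] = PHASE_LABELS
    landmark_subset: tuple[str, ...] = LANDMARK_LABELS
    uninformative_subset: tuple[str, ...] = UNINFORMATIVE_LABELS
    instrument_subset: tuple[str, ...] = INSTRUMENT_LABELS

    def __post_init__(self) -> None:
        if len(self.image_labels) != 10:
            raise ValueError("taxonomy requires exactly 10 image labels")
        if len(set(self.image_labels)) != len(self.image_labels):
            raise ValueError("image label names must be unique")
        image = set(self.image_labels)
        subsets = {
            "landmark_subset": set(self.landmark_subset),
            "uninformative_subset": set(self.uninformative_subset),
            "instrument_subset": set(self.instrument_subset),
        }
        for name, sub in subsets.items():
            if not sub <= image:
                raise ValueError(f"{name} must be a subset of image_labels")
        names = list(subsets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if subsets[a] & subsets[b]:
                    raise ValueError(f"{a} and {b} must be disjoint")


#: Shared default taxonomy; constructing it validates the subset invariants
#: at import time.
TAXONOMY = LabelTaxonomy()
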