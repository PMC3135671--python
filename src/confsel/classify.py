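"""Binding-mode classification of per-frame docking outcomes.

The receptor samples three principal pocket states and the docking
outcome of a frame identifies which one it was in:

* **closed** — no pose could be placed at all (no score);
* **deep** — a pose was placed and its nearest atom lies strictly
  under the deep threshold (default 5 Å) from the key S1′ carbonyl
  oxygen (Leu115 in MMP-3, Leu111 in MMP-2 numbering);
* **superficial** — a pose was placed but sits at or beyond the
  threshold.

The boundary is strict: a key distance of exactly 5.0 Å is superficial.
The key distance is a within-frame distance, so classification is
invariant to how the ensemble was aligned.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .docking import PoseRecord
from .errors import PipelineInputError, SelectionError
from .frames import AtomDescriptor, ConformationFrame
from .synthetic import KEY_OXYGEN_DESCRIPTOR

__all__ = ["BindingState", "ClassificationRule", "FrameClassification",
           "classify_frame", "classify_ensemble"]

logger = logging.getLogger(__name__)


class BindingState(str, Enum):
    CLOSED = "closed"
    SUPERFICIAL = "superficial"
    DEEP = "deep"


@dataclass(frozen=True)
class ClassificationRule:
    """Key-atom descriptor plus the strict deep-binding threshold (Å)."""

    key_atom: AtomDescriptor = KEY_OXYGEN_DESCRIPTOR
    deep_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.deep_threshold <= 0:
            raise PipelineInputError("deep_threshold must be positive")


@dataclass(frozen=True)
class FrameClassification:
    frame_index: int
    state: BindingState
    key_distance: float | None = None


def _recompute_key_distance(record: PoseRecord, frame: ConformationFrame,
                            rule: ClassificationRule) -> float:
    key = frame.atom_coord(rule.key_atom)
    return float(np.min(np.linalg.norm(record.coords - key, axis=1)))


def classify_frame(
    record: PoseRecord,
    frame: ConformationFrame | None = None,
    rule: ClassificationRule | None = None,
) -> FrameClassification:
    """Classify one frame's docking outcome.

    Uses the record's stored key distance when present; otherwise
    recomputes it from the pose geometry (minimum over fragment atoms of
    the distance to the key oxygen).  When both are available and
    disagree by more than 0.01 Å a warning is logged and the stored
    value wins.
    """
    rule = rule or ClassificationRule()
    if not record.placed:
        return FrameClassification(record.frame_index, BindingState.CLOSED)

    key_distance = record.key_distance
    if record.coords is not None and frame is not None:
        recomputed = _recompute_key_distance(record, frame, rule)
        if key_distance is None:
            key_distance = recomputed
        elif abs(key_distance - recomputed) > 0.01:
            logger.warning(
                "frame %d: stored key distance %.3f Å disagrees with geometry %.3f Å",
                record.frame_index, key_distance, recomputed,
            )
    if key_distance is None:
        raise PipelineInputError(
            f"frame {record.frame_index}: placed record has no key distance and "
            "no geometry to recompute it from"
        )

    state = (BindingState.DEEP if key_distance < rule.deep_threshold
             else BindingState.SUPERFICIAL)
    return FrameClassification(record.frame_index, state, key_distance)


def classify_ensemble(
    records: list[PoseRecord],
    frames: list[ConformationFrame] | None = None,
    rule: ClassificationRule | None = None,
) -> tuple[list[FrameClassification], dict[BindingState, int]]:
    """Classify every record; returns classifications plus state counts.

    ``frames``, when given, must be indexable by each record's
    ``frame_index`` (used only to recompute missing key distances).
    """
    rule = rule or ClassificationRule()
    indices = [r.frame_index for r in records]
    if len(set(indices)) != len(indices):
        raise PipelineInputError("records carry duplicate frame indices")

    out = []
    for record in records:
        frame = None
        if frames is not None and record.coords is not None:
            if not 0 <= record.frame_index < len(frames):
                raise PipelineInputError(
                    f"record frame_index {record.frame_index} outside ensemble "
                    f"of {len(frames)} frames"
                )
            frame = frames[record.frame_index]
        out.append(classify_frame(record, frame, rule))

    counts = Counter(c.state for c in out)
    return out, {state: counts.get(state, 0) for state in BindingState}
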