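"""Vertebral level numbering (T1-L5) under whole and truncated fields of view.

Anchoring rule: when the pelvis is visible, the bilateral PSIS keypoints
define a horizontal reference line and the most caudal vertebra whose
box center lies superior to that line is L5; the remaining visible
vertebrae are numbered superiorly (L4 ... T1).  Without a pelvis the
most superior visible vertebra is taken to be T1 and numbering proceeds
inferiorly — an assumption, so a standing warning is attached.

The assignment is verified (advisory only, never re-labelled) by the
sequential distribution of vertebral aspect ratios: thoracic vertebrae
carry a larger height-to-width ratio than lumbar vertebrae.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .annotations import SpineAnnotation
from .errors import AnnotationValidationError, LevelAssignmentError

__all__ = ["LEVEL_NAMES", "Anchor", "LevelAssignment", "assign_levels",
           "aspect_ratio_check"]

#: Clinical convention: 12 thoracic + 5 lumbar levels, cranial to caudal.
LEVEL_NAMES: tuple[str, ...] = tuple(
    [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]
)
_LEVEL_INDEX = {name: i for i, name in enumerate(LEVEL_NAMES)}
_L5 = _LEVEL_INDEX["L5"]

TOP_DOWN_WARNING = (
    "top_down anchor assumes the most superior visible vertebra is T1"
)


class Anchor(str, Enum):
    PSIS = "psis"
    TOP_DOWN = "top_down"


@dataclass
class LevelAssignment:
    """Level labels aligned index-for-index with ``ann.vertebrae``."""

    levels: list[str]
    anchor: Anchor
    verified: bool = True
    warnings: list[str] = field(default_factory=list)


def assign_levels(ann: SpineAnnotation) -> LevelAssignment:
    """Label every visible vertebra with its T1-L5 level name.

    Raises :class:`LevelAssignmentError` when no vertebra lies above the
    PSIS line or when the visible count overflows the available levels
    from the anchor.
    """
    n = len(ann.vertebrae)
    if n < 1:
        raise LevelAssignmentError("no vertebrae to label")
    if n > 17:
        raise AnnotationValidationError(f"{n} vertebrae exceed the 17-level convention")

    if ann.pelvis is not None:
        line_y = ann.pelvis.line_y()
        anchor_idx = None
        for i in range(n - 1, -1, -1):
            if ann.vertebrae[i].bbox.cy < line_y:
                anchor_idx = i
                break
        if anchor_idx is None:
            raise LevelAssignmentError(
                "pelvis present but no vertebra lies above the PSIS line"
            )
        # vertebra anchor_idx is L5; count upward from it
        first_level = _L5 - anchor_idx
        if first_level < 0:
            raise LevelAssignmentError(
                f"{anchor_idx + 1} vertebrae above L5 exceed the T1-L5 range"
            )
        if anchor_idx < n - 1:
            # vertebrae below the L5 anchor have no level in T1-L5
            raise LevelAssignmentError(
                f"{n - 1 - anchor_idx} vertebrae inferior to the L5 anchor"
            )
        levels = [LEVEL_NAMES[first_level + k] for k in range(n)]
        return LevelAssignment(levels=levels, anchor=Anchor.PSIS)

    if n > len(LEVEL_NAMES):
        raise LevelAssignmentError("more visible vertebrae than levels from T1")
    levels = [LEVEL_NAMES[k] for k in range(n)]
    return LevelAssignment(
        levels=levels, anchor=Anchor.TOP_DOWN, warnings=[TOP_DOWN_WARNING]
    )


def aspect_ratio_check(
    ann: SpineAnnotation, assignment: LevelAssignment
) -> LevelAssignment:
    """Advisory verification of an assignment via box aspect ratios.

    ``verified`` stays true when either group is absent (vacuous) or the
    mean height/width over thoracic-labelled vertebrae exceeds that over
    lumbar-labelled ones; a failure adds a warning but never re-labels.
    Returns the updated assignment (mutated in place).
    """
    thoracic: list[float] = []
    lumbar: list[float] = []
    for v, level in zip(ann.vertebrae, assignment.levels):
        ratio = v.aspect_ratio()  # raises on zero-width box
        (thoracic if level.startswith("T") else lumbar).append(ratio)
    if thoracic and lumbar:
        ok = sum(thoracic) / len(thoracic) > sum(lumbar) / len(lumbar)
    else:
        ok = True
    assignment.verified = ok
    if not ok:
        assignment.warnings.append(
            "aspect-ratio check failed: thoracic mean h/w not greater than lumbar"
        )
    return assignment
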