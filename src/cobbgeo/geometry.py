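"""Endplate angles, Cobb angles and the end-vertebra search.

The measurement chain, all in the y-down image frame:

* superior endplate angle  alpha = atan2(rt.y - lt.y, rt.x - lt.x)
* inferior endplate angle  beta  = atan2(rb.y - lb.y, rb.x - lb.x)
* both normalized to the half-open interval [-90, 90) degrees
* vertebral tilt           theta = (alpha + beta) / 2
* Cobb angle of a candidate end-vertebra pair (i, j), i superior:
  C(i, j) = |alpha_i - beta_j|, with the difference wrapped to
  (-90, 90] first so that near-vertical endplates that normalize to
  opposite signs still yield the acute inter-line angle.

The end-vertebra search exhaustively evaluates C(i, j) over all pairs
with j - i >= min_span inside an interval and keeps the argmax if it
reaches min_angle; multi-curve decomposition re-runs the search on the
superior interval [0, i] and inferior interval [j, N-1], sharing the
primary end vertebrae, for at most three curves in total.

A positive angle means the right end of the line sits inferior to the
left end (y grows downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .annotations import Point2D, SpineAnnotation, VertebraKeypoints
from .errors import CobbGeoError, DegenerateVertebraError

__all__ = [
    "Severity",
    "VertebraAngles",
    "CurveMeasurement",
    "SearchConfig",
    "SearchAudit",
    "normalize_angle",
    "endplate_angles",
    "vertebral_tilt",
    "cobb_pair",
    "angles_from_annotation",
    "find_end_vertebrae",
    "decompose_curves",
    "bilateral_tilt",
    "classify_severity",
]

_DEGENERATE_EPS = 1e-9  # px; endplate segments shorter than this are rejected


class Severity(str, Enum):
    """Clinical Cobb-angle strata; >10 deg defines scoliosis."""

    SUB_THRESHOLD = "sub_threshold"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class VertebraAngles:
    """Per-vertebra angle record (degrees, y-down frame)."""

    alpha: float
    beta: float
    theta: float
    index: int


@dataclass
class CurveMeasurement:
    """One scoliotic curve bounded by its end vertebrae."""

    upper_idx: int
    lower_idx: int
    cobb_deg: float
    severity: Severity
    signed_delta: float = 0.0  # wrapped alpha_i - beta_j, sign retained for audit
    upper_level: str | None = None
    lower_level: str | None = None


@dataclass(frozen=True)
class SearchConfig:
    """End-vertebra search parameters.

    min_span
        Minimum index separation j - i between end vertebrae; guards
        against short-range spurious pairs.
    min_angle
        Degrees; the search reports nothing below this Cobb magnitude.
    max_curves
        Cap on the number of curves after decomposition (1-3).
    """

    min_span: int = 3
    min_angle: float = 5.0
    max_curves: int = 3

    def __post_init__(self) -> None:
        if self.min_span < 1:
            raise CobbGeoError("min_span must be >= 1")
        if not self.min_angle > 0:
            raise CobbGeoError("min_angle must be positive")
        if self.max_curves not in (1, 2, 3):
            raise CobbGeoError("max_curves must be 1, 2 or 3")


@dataclass
class SearchAudit:
    """Trace of one decomposition run, for the report's audit trail."""

    candidate_pairs: int = 0
    tie_events: int = 0
    skipped_indices: list[int] = field(default_factory=list)


def normalize_angle(raw: float) -> float:
    """Map any angle (degrees) to the half-open interval [-90, 90).

    Equivalent mod 180; the boundary +90 maps to -90 so vertical lines
    have a single representation.
    """
    if not math.isfinite(raw):
        raise CobbGeoError(f"non-finite angle {raw!r}")
    return (raw + 90.0) % 180.0 - 90.0


def _segment_angle(a: Point2D, b: Point2D) -> float:
    dx, dy = b.x - a.x, b.y - a.y
    if math.hypot(dx, dy) < _DEGENERATE_EPS:
        raise DegenerateVertebraError("coincident endplate corner pair")
    return normalize_angle(math.degrees(math.atan2(dy, dx)))


def endplate_angles(v: VertebraKeypoints) -> tuple[float, float]:
    """Superior and inferior endplate angles (degrees) of one vertebra."""
    try:
        alpha = _segment_angle(v.lt, v.rt)
        beta = _segment_angle(v.lb, v.rb)
    except DegenerateVertebraError as exc:
        raise DegenerateVertebraError(str(exc)) from None
    return alpha, beta


def vertebral_tilt(alpha: float, beta: float) -> float:
    """Vertebral tilt: the arithmetic mean of the two endplate angles."""
    return (alpha + beta) / 2.0


def _wrap_half(delta: float) -> float:
    """Wrap an angle difference to (-90, 90]."""
    w = (delta + 90.0) % 180.0 - 90.0
    if w == -90.0 and delta != -90.0:
        # keep the (-90, 90] convention; magnitude is unaffected either way
        w = 90.0
    return w


def cobb_pair(alpha_i: float, beta_j: float) -> float:
    """Cobb magnitude |alpha_i - beta_j| of a candidate pair, in [0, 90].

    The difference is wrapped to (-90, 90] first: two lines meet at an
    acute angle even when their normalized orientations straddle +/-90.
    """
    return abs(_wrap_half(alpha_i - beta_j))


def angles_from_annotation(
    ann: SpineAnnotation, audit: SearchAudit | None = None
) -> list[Optional[VertebraAngles]]:
    """Angle records for every vertebra, ``None`` where skipped.

    A vertebra is skipped (excluded from end-vertebra candidacy without
    splitting the search interval) when any corner keypoint is flagged
    absent or an endplate segment is degenerate.
    """
    out: list[Optional[VertebraAngles]] = []
    for i, v in enumerate(ann.vertebrae):
        if not v.corners_present():
            out.append(None)
            if audit is not None:
                audit.skipped_indices.append(i)
            continue
        try:
            alpha, beta = endplate_angles(v)
        except DegenerateVertebraError:
            out.append(None)
            if audit is not None:
                audit.skipped_indices.append(i)
            continue
        out.append(VertebraAngles(alpha, beta, vertebral_tilt(alpha, beta), i))
    return out


def find_end_vertebrae(
    angles: Sequence[Optional[VertebraAngles]],
    interval: tuple[int, int] | None = None,
    cfg: SearchConfig = SearchConfig(),
    audit: SearchAudit | None = None,
) -> CurveMeasurement | None:
    """Exhaustive argmax of C(i, j) over one interval.

    Evaluates every pair s <= i < j <= e with j - i >= cfg.min_span,
    skipping ``None`` entries; returns the maximizing pair when the
    maximum reaches cfg.min_angle, otherwise ``None``.  Ties are broken
    by the lexicographically smallest (i, j).
    """
    if not angles:
        return None
    s, e = interval if interval is not None else (0, len(angles) - 1)
    s, e = max(s, 0), min(e, len(angles) - 1)

    best: tuple[float, int, int] | None = None
    n_ties = 0
    n_pairs = 0
    for i in range(s, e + 1):
        ai = angles[i]
        if ai is None:
            continue
        for j in range(i + cfg.min_span, e + 1):
            bj = angles[j]
            if bj is None:
                continue
            n_pairs += 1
            c = cobb_pair(ai.alpha, bj.beta)
            if best is None or c > best[0]:
                best = (c, i, j)
                n_ties = 0
            elif c == best[0]:
                n_ties += 1  # lexicographic order of iteration keeps the first
    if audit is not None:
        audit.candidate_pairs += n_pairs
        audit.tie_events += n_ties
    if best is None or best[0] < cfg.min_angle:
        return None
    c, i, j = best
    ai = angles[i]
    bj = angles[j]
    assert ai is not None and bj is not None
    return CurveMeasurement(
        upper_idx=i,
        lower_idx=j,
        cobb_deg=c,
        severity=classify_severity(c),
        signed_delta=_wrap_half(ai.alpha - bj.beta),
    )


def decompose_curves(
    angles: Sequence[Optional[VertebraAngles]],
    cfg: SearchConfig = SearchConfig(),
    audit: SearchAudit | None = None,
) -> list[CurveMeasurement]:
    """Primary search plus one pass over each flanking interval.

    The primary curve is found over the whole sequence; the superior
    interval [0, i] and inferior interval [j, N-1] are then each searched
    once (the primary end vertebrae remain candidates, so adjacent curves
    may share a transitional vertebra).  Recursion stops there; at most
    ``cfg.max_curves`` curves are returned, ordered cranially to caudally.
    When the cap forces a choice among the flanking curves, the larger
    Cobb magnitude wins (tie: the more cranial).
    """
    if not angles:
        return []
    n = len(angles)
    primary = find_end_vertebrae(angles, (0, n - 1), cfg, audit)
    if primary is None:
        return []
    curves = [primary]
    if cfg.max_curves > 1:
        flanks: list[CurveMeasurement] = []
        sup = find_end_vertebrae(angles, (0, primary.upper_idx), cfg, audit)
        if sup is not None:
            flanks.append(sup)
        inf = find_end_vertebrae(angles, (primary.lower_idx, n - 1), cfg, audit)
        if inf is not None:
            flanks.append(inf)
        flanks.sort(key=lambda c: (-c.cobb_deg, c.upper_idx))
        curves.extend(flanks[: cfg.max_curves - 1])
    curves.sort(key=lambda c: c.upper_idx)
    return curves


def bilateral_tilt(left: Point2D, right: Point2D) -> float:
    """Coronal tilt (degrees) of a bilateral landmark line.

    Positive when the right (larger-x) point sits inferior to the left
    point.  Used for the pelvic PSIS line and any caller-supplied
    shoulder pair.
    """
    if not left.x < right.x:
        raise CobbGeoError("expected left.x < right.x for a bilateral pair")
    return _segment_angle(left, right)


def classify_severity(cobb_deg: float) -> Severity:
    """Map a Cobb magnitude to the clinical strata.

    <=10 sub-threshold (below the scoliosis definition), (10, 20) mild,
    [20, 35] moderate, >35 severe.
    """
    if not math.isfinite(cobb_deg) or cobb_deg < 0:
        raise CobbGeoError(f"Cobb magnitude must be finite and >= 0, got {cobb_deg!r}")
    if cobb_deg <= 10.0:
        return Severity.SUB_THRESHOLD
    if cobb_deg < 20.0:
        return Severity.MILD
    if cobb_deg <= 35.0:
        return Severity.MODERATE
    return Severity.SEVERE
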