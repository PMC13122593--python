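"""Keypoint annotation data model and pose-label / JSON readers and writers.

Coordinate frame
----------------
All coordinates are image-frame pixels: origin at the top-left corner,
x increasing rightward, y increasing DOWNWARD.  Every angle elsewhere in
the package is defined in this frame, so a positive endplate angle means
the right end of the segment sits inferior (lower on the image) to the
left end.

"Left"/"right" in keypoint names refer to image x-order, never to the
patient's anatomical side.

On-disk formats
---------------
Pose-label text dialect, one file per image, one line per object::

    <class> <cx> <cy> <w> <h>  x1 y1 v1  x2 y2 v2 ...

where class 0 is a vertebra (5 keypoint triplets: top-left, top-right,
bottom-left, bottom-right corner, then spinous-process midpoint), class 1
is the pelvis (2 triplets: left PSIS, right PSIS), all coordinates
normalized to [0, 1] by the image dimensions, and v is a visibility flag
(0 = absent, 1 = occluded, 2 = visible).

The JSON schema mirrors :class:`SpineAnnotation` field for field.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import AnnotationValidationError, PoseLabelParseError

__all__ = [
    "Point2D",
    "BoundingBox",
    "VertebraKeypoints",
    "PelvisLandmarks",
    "SpineAnnotation",
    "ValidationIssue",
    "read_pose_labels",
    "write_pose_labels",
    "read_json_annotation",
    "write_json_annotation",
    "validate_annotation",
]

VERTEBRA_CLASS = 0
PELVIS_CLASS = 1

FOV_VALUES = ("whole", "thoracic", "lumbar", "unknown")


@dataclass(frozen=True)
class Point2D:
    """A point in image pixels (y grows downward)."""

    x: float
    y: float

    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: center + extent, pixels."""

    cx: float
    cy: float
    width: float
    height: float


@dataclass(frozen=True)
class VertebraKeypoints:
    """One vertebra: four endplate corners, spinous-process point, box.

    ``visibility`` holds the per-keypoint flags in the keypoint order
    (lt, rt, lb, rb, sp); only flag 0 (absent) changes behaviour: any
    absent corner excludes the vertebra from angle computation.
    """

    lt: Point2D
    rt: Point2D
    lb: Point2D
    rb: Point2D
    sp: Point2D
    bbox: BoundingBox
    visibility: tuple[int, int, int, int, int] = (2, 2, 2, 2, 2)
    conf: float | None = None

    def corners(self) -> tuple[Point2D, Point2D, Point2D, Point2D]:
        return (self.lt, self.rt, self.lb, self.rb)

    def corners_present(self) -> bool:
        """True iff no corner keypoint carries visibility flag 0."""
        return all(v != 0 for v in self.visibility[:4])

    def aspect_ratio(self) -> float:
        """Bounding-box height / width."""
        if self.bbox.width <= 0:
            raise AnnotationValidationError("zero-width bounding box")
        return self.bbox.height / self.bbox.width


@dataclass(frozen=True)
class PelvisLandmarks:
    """Bilateral PSIS endpoints; 'left' = smaller image x."""

    psis_left: Point2D
    psis_right: Point2D
    bbox: BoundingBox | None = None

    def line_y(self) -> float:
        """y-coordinate of the horizontal PSIS reference line."""
        return 0.5 * (self.psis_left.y + self.psis_right.y)


@dataclass
class SpineAnnotation:
    """All keypoint objects of one radiograph, craniocaudally ordered.

    ``vertebrae[0]`` is the most superior vertebra.  Ordering is canonical
    (ascending bbox center-y, ties by center-x) and is re-established by
    the readers regardless of line order on disk.
    """

    vertebrae: list[VertebraKeypoints]
    pelvis: PelvisLandmarks | None = None
    image_width: int = 0
    image_height: int = 0
    fov: str = "unknown"
    source_id: str = ""

    def sorted(self) -> "SpineAnnotation":
        """Copy with vertebrae in canonical craniocaudal order."""
        order = sorted(self.vertebrae, key=lambda v: (v.bbox.cy, v.bbox.cx))
        return replace(self, vertebrae=order)


@dataclass(frozen=True)
class ValidationIssue:
    """Machine-readable validation finding."""

    code: str
    index: int | None
    message: str


# ---------------------------------------------------------------------------
# pose-label text dialect
# ---------------------------------------------------------------------------

_N_VERT_FIELDS = 1 + 4 + 5 * 3
_N_PELVIS_FIELDS = 1 + 4 + 2 * 3


def _parse_floats(tokens: Sequence[str], line_no: int) -> list[float]:
    try:
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise PoseLabelParseError(f"non-numeric token: {exc}", line_no) from None


def _check_normalized(values: Iterable[float], line_no: int) -> None:
    for v in values:
        if not math.isfinite(v) or v < 0.0 or v > 1.0:
            raise PoseLabelParseError(
                f"normalized value {v!r} outside [0, 1]", line_no
            )


def read_pose_labels(
    path: str | Path,
    image_width: int,
    image_height: int,
    *,
    fov: str = "unknown",
    source_id: str | None = None,
) -> SpineAnnotation:
    """Read a pose-label text file into a :class:`SpineAnnotation`.

    Coordinates are denormalized to pixels using the supplied image
    dimensions.  Vertebrae are returned in canonical craniocaudal order
    independent of line order; at most one pelvis object is allowed.
    """
    path = Path(path)
    if image_width <= 0 or image_height <= 0:
        raise AnnotationValidationError("image dimensions must be positive")
    vertebrae: list[VertebraKeypoints] = []
    pelvis: PelvisLandmarks | None = None

    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        values = _parse_floats(tokens, line_no)
        cls = values[0]
        if cls != int(cls) or int(cls) not in (VERTEBRA_CLASS, PELVIS_CLASS):
            raise PoseLabelParseError(f"unknown class id {cls!r}", line_no)
        cls = int(cls)

        expected = _N_VERT_FIELDS if cls == VERTEBRA_CLASS else _N_PELVIS_FIELDS
        if len(values) != expected:
            raise PoseLabelParseError(
                f"class {cls} expects {expected} fields, got {len(values)}",
                line_no,
            )
        coords = values[1:5] + [
            v for k, v in enumerate(values[5:]) if k % 3 != 2
        ]
        _check_normalized(coords, line_no)

        cx, cy, w, h = values[1:5]
        bbox = BoundingBox(
            cx * image_width, cy * image_height, w * image_width, h * image_height
        )
        triplets = [values[5 + 3 * k : 8 + 3 * k] for k in range((len(values) - 5) // 3)]
        pts = [Point2D(t[0] * image_width, t[1] * image_height) for t in triplets]
        flags = tuple(int(t[2]) for t in triplets)

        if cls == VERTEBRA_CLASS:
            vertebrae.append(
                VertebraKeypoints(
                    lt=pts[0], rt=pts[1], lb=pts[2], rb=pts[3], sp=pts[4],
                    bbox=bbox, visibility=flags,  # type: ignore[arg-type]
                )
            )
        else:
            if pelvis is not None:
                raise AnnotationValidationError(
                    f"line {line_no}: more than one pelvis object"
                )
            pelvis = PelvisLandmarks(psis_left=pts[0], psis_right=pts[1], bbox=bbox)

    ann = SpineAnnotation(
        vertebrae=vertebrae,
        pelvis=pelvis,
        image_width=image_width,
        image_height=image_height,
        fov=fov,
        source_id=source_id if source_id is not None else path.stem,
    )
    return ann.sorted()


def _fmt(v: float) -> str:
    return f"{v:.6f}"


def write_pose_labels(ann: SpineAnnotation, path: str | Path) -> None:
    """Write ``ann`` in the pose-label dialect (6-decimal normalized).

    Vertebrae are emitted superior to inferior, then the pelvis.
    """
    if ann.image_width <= 0 or ann.image_height <= 0:
        raise AnnotationValidationError("image dimensions must be set before writing")
    W, H = ann.image_width, ann.image_height
    lines: list[str] = []
    for v in ann.sorted().vertebrae:
        parts = [
            str(VERTEBRA_CLASS),
            _fmt(v.bbox.cx / W), _fmt(v.bbox.cy / H),
            _fmt(v.bbox.width / W), _fmt(v.bbox.height / H),
        ]
        for p, flag in zip((v.lt, v.rt, v.lb, v.rb, v.sp), v.visibility):
            parts += [_fmt(p.x / W), _fmt(p.y / H), str(flag)]
        lines.append(" ".join(parts))
    if ann.pelvis is not None:
        p = ann.pelvis
        bbox = p.bbox
        if bbox is None:
            # synthesize a tight box around the PSIS pair
            xs = (p.psis_left.x, p.psis_right.x)
            ys = (p.psis_left.y, p.psis_right.y)
            bbox = BoundingBox(
                (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2,
                max(max(xs) - min(xs), 1.0), max(max(ys) - min(ys), 1.0),
            )
        parts = [
            str(PELVIS_CLASS),
            _fmt(bbox.cx / W), _fmt(bbox.cy / H),
            _fmt(bbox.width / W), _fmt(bbox.height / H),
        ]
        for pt in (p.psis_left, p.psis_right):
            parts += [_fmt(pt.x / W), _fmt(pt.y / H), "2"]
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------

def _point_to_obj(p: Point2D) -> dict:
    return {"x": p.x, "y": p.y}


def _point_from_obj(o: dict) -> Point2D:
    return Point2D(float(o["x"]), float(o["y"]))


def _bbox_to_obj(b: BoundingBox) -> dict:
    return {"cx": b.cx, "cy": b.cy, "width": b.width, "height": b.height}


def _bbox_from_obj(o: dict) -> BoundingBox:
    return BoundingBox(float(o["cx"]), float(o["cy"]),
                       float(o["width"]), float(o["height"]))


def annotation_to_dict(ann: SpineAnnotation) -> dict:
    """JSON-ready dict mirroring the annotation field for field."""
    obj: dict = {
        "image_width": ann.image_width,
        "image_height": ann.image_height,
        "fov": ann.fov,
        "source_id": ann.source_id,
        "vertebrae": [
            {
                "lt": _point_to_obj(v.lt), "rt": _point_to_obj(v.rt),
                "lb": _point_to_obj(v.lb), "rb": _point_to_obj(v.rb),
                "sp": _point_to_obj(v.sp),
                "bbox": _bbox_to_obj(v.bbox),
                "visibility": list(v.visibility),
            }
            for v in ann.sorted().vertebrae
        ],
        "pelvis": None,
    }
    if ann.pelvis is not None:
        obj["pelvis"] = {
            "psis_left": _point_to_obj(ann.pelvis.psis_left),
            "psis_right": _point_to_obj(ann.pelvis.psis_right),
            "bbox": _bbox_to_obj(ann.pelvis.bbox) if ann.pelvis.bbox else None,
        }
    return obj


def annotation_from_dict(obj: dict) -> SpineAnnotation:
    vertebrae = [
        VertebraKeypoints(
            lt=_point_from_obj(v["lt"]), rt=_point_from_obj(v["rt"]),
            lb=_point_from_obj(v["lb"]), rb=_point_from_obj(v["rb"]),
            sp=_point_from_obj(v["sp"]),
            bbox=_bbox_from_obj(v["bbox"]),
            visibility=tuple(v.get("visibility", (2, 2, 2, 2, 2))),  # type: ignore[arg-type]
        )
        for v in obj["vertebrae"]
    ]
    pelvis = None
    if obj.get("pelvis") is not None:
        p = obj["pelvis"]
        pelvis = PelvisLandmarks(
            psis_left=_point_from_obj(p["psis_left"]),
            psis_right=_point_from_obj(p["psis_right"]),
            bbox=_bbox_from_obj(p["bbox"]) if p.get("bbox") else None,
        )
    ann = SpineAnnotation(
        vertebrae=vertebrae,
        pelvis=pelvis,
        image_width=int(obj["image_width"]),
        image_height=int(obj["image_height"]),
        fov=obj.get("fov", "unknown"),
        source_id=obj.get("source_id", ""),
    )
    return ann.sorted()


def write_json_annotation(ann: SpineAnnotation, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(annotation_to_dict(ann), indent=2, sort_keys=True) + "\n"
    )


def read_json_annotation(path: str | Path) -> SpineAnnotation:
    return annotation_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_annotation(ann: SpineAnnotation) -> list[ValidationIssue]:
    """Report invariant violations; never raises.

    An empty list means the annotation satisfies every structural
    invariant (corner x-order, positive boxes, superior top edge,
    craniocaudal order, pelvis below the lowest vertebra, counts).
    """
    issues: list[ValidationIssue] = []

    def add(code: str, index: int | None, msg: str) -> None:
        issues.append(ValidationIssue(code, index, msg))

    if not (0 <= len(ann.vertebrae) <= 17):
        add("VERTEBRA_COUNT", None,
            f"{len(ann.vertebrae)} vertebrae (expected at most 17)")

    for i, v in enumerate(ann.vertebrae):
        pts = [v.lt, v.rt, v.lb, v.rb, v.sp]
        if not all(p.is_finite() for p in pts):
            add("NONFINITE", i, "non-finite keypoint coordinate")
            continue
        if not v.lt.x < v.rt.x:
            add("CORNER_ORDER", i, "top corners out of x-order (lt.x >= rt.x)")
        if not v.lb.x < v.rb.x:
            add("CORNER_ORDER", i, "bottom corners out of x-order (lb.x >= rb.x)")
        if v.bbox.width <= 0 or v.bbox.height <= 0:
            add("BBOX_NONPOSITIVE", i, "bounding box has non-positive extent")
        top_y = 0.5 * (v.lt.y + v.rt.y)
        bot_y = 0.5 * (v.lb.y + v.rb.y)
        if not top_y < bot_y:
            add("EDGE_ORDER", i, "top edge not superior to bottom edge")

    for i in range(1, len(ann.vertebrae)):
        prev, cur = ann.vertebrae[i - 1], ann.vertebrae[i]
        if cur.bbox.cy < prev.bbox.cy:
            add("VERTEBRA_ORDER", i, "vertebrae not in ascending center-y order")
        elif cur.bbox.cy == prev.bbox.cy:
            add("CENTER_TIE", i, "degenerate center-y tie (order broken by center-x)")

    if ann.pelvis is not None:
        p = ann.pelvis
        if not (p.psis_left.is_finite() and p.psis_right.is_finite()):
            add("NONFINITE", None, "non-finite PSIS coordinate")
        elif not p.psis_left.x < p.psis_right.x:
            add("PELVIS_ORDER", None, "PSIS points out of x-order")
        if ann.vertebrae and p.psis_left.is_finite() and p.psis_right.is_finite():
            lowest = ann.vertebrae[-1]
            if not p.line_y() > lowest.bbox.cy:
                add("PELVIS_POSITION", None,
                    "PSIS line not inferior to the lowest vertebra center")

    return issues
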