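"""Auditable visual overlays: keypoints, measurement lines, level labels.

Rendering is content-based and deterministic (Pillow with its built-in
bitmap font, fixed colors): every number drawn on the canvas is taken
verbatim from the report, so overlay and JSON can never disagree.
"""

from __future__ import annotations

import math
from pathlib import Path

from PIL import Image, ImageDraw

from .annotations import SpineAnnotation
from .errors import CobbGeoError
from .report import MeasurementReport

__all__ = ["render_overlay"]

_KP_COLOR = (0, 160, 255)
_ENDPLATE_COLOR = (255, 60, 60)
_COBB_LINE_COLOR = (255, 160, 0)
_PSIS_COLOR = (60, 200, 60)
_TEXT_COLOR = (20, 20, 20)
_LEVEL_COLOR = (90, 90, 90)


def _extended(p, q, width: float):
    """Extend segment p->q across the full drawing width."""
    dx, dy = q.x - p.x, q.y - p.y
    norm = math.hypot(dx, dy)
    dx, dy = dx / norm, dy / norm
    t = width  # long enough to cross the canvas
    return (p.x - t * dx, p.y - t * dy, q.x + t * dx, q.y + t * dy)


def render_overlay(
    report: MeasurementReport,
    ann: SpineAnnotation,
    image: str | Path | Image.Image | None = None,
    out_path: str | Path = "overlay.png",
) -> Path:
    """Draw the measurement overlay and save it as PNG.

    Keypoints, the endplate segments of every curve's end vertebrae with
    extended Cobb measurement lines, level labels, the PSIS line (when a
    pelvis exists) and a text block of all reported angles are drawn on
    the radiograph when given, else on a blank canvas of the
    annotation's dimensions.
    """
    W, H = ann.image_width, ann.image_height
    if W <= 0 or H <= 0:
        raise CobbGeoError("annotation image dimensions must be set")
    if image is None:
        canvas = Image.new("RGB", (W, H), (255, 255, 255))
    else:
        img = image if isinstance(image, Image.Image) else Image.open(image)
        if img.size != (W, H):
            raise CobbGeoError(
                f"raster size {img.size} != annotation size {(W, H)}"
            )
        canvas = img.convert("RGB")
    draw = ImageDraw.Draw(canvas)

    r = max(2, round(min(W, H) / 400))
    for v in ann.vertebrae:
        for p in (v.lt, v.rt, v.lb, v.rb, v.sp):
            draw.ellipse((p.x - r, p.y - r, p.x + r, p.y + r), fill=_KP_COLOR)

    for rec in report.vertebrae:
        if rec.level:
            v = ann.vertebrae[rec.index]
            draw.text(
                (v.bbox.cx + v.bbox.width * 0.7, v.bbox.cy - 5),
                rec.level, fill=_LEVEL_COLOR,
            )

    for c in report.curves:
        upper = ann.vertebrae[c.upper_idx]
        lower = ann.vertebrae[c.lower_idx]
        draw.line((upper.lt.x, upper.lt.y, upper.rt.x, upper.rt.y),
                  fill=_ENDPLATE_COLOR, width=3)
        draw.line((lower.lb.x, lower.lb.y, lower.rb.x, lower.rb.y),
                  fill=_ENDPLATE_COLOR, width=3)
        draw.line(_extended(upper.lt, upper.rt, W / 3), fill=_COBB_LINE_COLOR, width=1)
        draw.line(_extended(lower.lb, lower.rb, W / 3), fill=_COBB_LINE_COLOR, width=1)

    if ann.pelvis is not None:
        p = ann.pelvis
        draw.line((p.psis_left.x, p.psis_left.y, p.psis_right.x, p.psis_right.y),
                  fill=_PSIS_COLOR, width=3)
        for pt in (p.psis_left, p.psis_right):
            draw.ellipse((pt.x - r, pt.y - r, pt.x + r, pt.y + r), fill=_PSIS_COLOR)

    lines = [f"source: {report.source_id}"]
    for c in report.curves:
        seg = (
            f"{c.upper_level or c.upper_idx}-{c.lower_level or c.lower_idx}"
        )
        lines.append(f"Cobb {seg}: {c.cobb_deg:.2f} deg ({c.severity.value})")
    if report.pelvic_tilt_deg is not None:
        lines.append(f"pelvic tilt: {report.pelvic_tilt_deg:.2f} deg")
    if report.shoulder_tilt_deg is not None:
        lines.append(f"shoulder tilt: {report.shoulder_tilt_deg:.2f} deg")
    if not report.curves:
        lines.append("no curve >= threshold")
    draw.multiline_text((10, 10), "\n".join(lines), fill=_TEXT_COLOR)

    out_path = Path(out_path)
    canvas.save(out_path, format="PNG")
    return out_path
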