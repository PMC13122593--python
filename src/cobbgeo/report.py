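"""End-to-end measurement: annotation in, auditable report out.

``measure`` composes the full chain — endplate angles, vertebral tilts,
multi-curve end-vertebra search, level numbering, pelvic tilt, severity
— into a :class:`MeasurementReport` that serializes to canonical JSON.
It is a pure function of (annotation, config): identical input yields
byte-identical JSON.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import SpineAnnotation, read_pose_labels, validate_annotation
from .errors import CobbGeoError, LevelAssignmentError
from .geometry import (
    CurveMeasurement,
    SearchAudit,
    SearchConfig,
    angles_from_annotation,
    bilateral_tilt,
    decompose_curves,
)
from .labeling import aspect_ratio_check, assign_levels

__all__ = ["SCHEMA_VERSION", "VertebraRecord", "MeasurementReport",
           "measure", "batch_measure"]

logger = logging.getLogger("cobbgeo")

SCHEMA_VERSION = "1.0"

#: validator codes that block measurement (geometry would be meaningless)
_BLOCKING_CODES = {"CORNER_ORDER", "EDGE_ORDER", "VERTEBRA_ORDER",
                   "BBOX_NONPOSITIVE", "NONFINITE", "VERTEBRA_COUNT",
                   "PELVIS_ORDER", "PELVIS_POSITION"}


@dataclass
class VertebraRecord:
    index: int
    level: str | None
    alpha: float | None
    beta: float | None
    theta: float | None
    skipped: bool


@dataclass
class MeasurementReport:
    """Per-image measurement output with a full audit trail."""

    source_id: str
    vertebrae: list[VertebraRecord]
    curves: list[CurveMeasurement]
    pelvic_tilt_deg: float | None
    shoulder_tilt_deg: float | None
    levels_anchor: str | None
    levels_verified: bool | None
    config: SearchConfig
    warnings: list[str] = field(default_factory=list)
    audit: SearchAudit = field(default_factory=SearchAudit)

    def primary_curve(self) -> CurveMeasurement | None:
        """Largest Cobb magnitude; ties resolved to the most cranial curve."""
        if not self.curves:
            return None
        return max(self.curves, key=lambda c: (c.cobb_deg, -c.upper_idx))

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "source_id": self.source_id,
            "config": {
                "min_span": self.config.min_span,
                "min_angle": self.config.min_angle,
                "max_curves": self.config.max_curves,
            },
            "vertebrae": [
                {
                    "index": v.index,
                    "level": v.level,
                    "alpha_deg": v.alpha,
                    "beta_deg": v.beta,
                    "theta_deg": v.theta,
                    "skipped": v.skipped,
                }
                for v in self.vertebrae
            ],
            "curves": [
                {
                    "upper_idx": c.upper_idx,
                    "lower_idx": c.lower_idx,
                    "upper_level": c.upper_level,
                    "lower_level": c.lower_level,
                    "cobb_deg": c.cobb_deg,
                    "signed_delta_deg": c.signed_delta,
                    "severity": c.severity.value,
                }
                for c in self.curves
            ],
            "pelvic_tilt_deg": self.pelvic_tilt_deg,
            "shoulder_tilt_deg": self.shoulder_tilt_deg,
            "levels_anchor": self.levels_anchor,
            "levels_verified": self.levels_verified,
            "warnings": list(self.warnings),
            "audit": {
                "candidate_pairs": self.audit.candidate_pairs,
                "tie_events": self.audit.tie_events,
                "skipped_indices": list(self.audit.skipped_indices),
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def measure(
    ann: SpineAnnotation,
    cfg: SearchConfig = SearchConfig(),
    shoulder_pair=None,
) -> MeasurementReport:
    """Measure one annotation: angles, curves, levels, tilts, severity.

    ``shoulder_pair`` may supply a bilateral (left, right) landmark pair
    for the shoulder coronal tilt; it is never inferred from the
    vertebral keypoints.  Raises on blocking validation issues.
    """
    issues = validate_annotation(ann)
    blocking = [i for i in issues if i.code in _BLOCKING_CODES]
    if blocking:
        detail = "; ".join(f"{i.code}@{i.index}: {i.message}" for i in blocking)
        raise CobbGeoError(f"annotation failed validation: {detail}")
    warnings = [f"{i.code}: {i.message}" for i in issues]

    audit = SearchAudit()
    angles = angles_from_annotation(ann, audit)
    curves = decompose_curves(angles, cfg, audit)

    levels = None
    anchor = None
    verified = None
    if ann.vertebrae:
        try:
            assignment = aspect_ratio_check(ann, assign_levels(ann))
            levels = assignment.levels
            anchor = assignment.anchor.value
            verified = assignment.verified
            warnings.extend(assignment.warnings)
        except LevelAssignmentError as exc:
            warnings.append(f"LEVELS: {exc}")

    records = []
    for i in range(len(ann.vertebrae)):
        a = angles[i]
        records.append(
            VertebraRecord(
                index=i,
                level=levels[i] if levels else None,
                alpha=a.alpha if a else None,
                beta=a.beta if a else None,
                theta=a.theta if a else None,
                skipped=a is None,
            )
        )
    for c in curves:
        if levels:
            c.upper_level = levels[c.upper_idx]
            c.lower_level = levels[c.lower_idx]

    pelvic = None
    if ann.pelvis is not None:
        pelvic = bilateral_tilt(ann.pelvis.psis_left, ann.pelvis.psis_right)
    shoulder = None
    if shoulder_pair is not None:
        shoulder = bilateral_tilt(shoulder_pair[0], shoulder_pair[1])

    return MeasurementReport(
        source_id=ann.source_id,
        vertebrae=records,
        curves=curves,
        pelvic_tilt_deg=pelvic,
        shoulder_tilt_deg=shoulder,
        levels_anchor=anchor,
        levels_verified=verified,
        config=cfg,
        warnings=warnings,
        audit=audit,
    )


def batch_measure(
    in_dir: str | Path,
    out_dir: str | Path,
    manifest: str | Path,
    cfg: SearchConfig = SearchConfig(),
    *,
    overlays: bool = False,
) -> tuple[int, int]:
    """Measure every pose-label file listed in the image-size manifest.

    The manifest is a CSV with at least ``source_id``, ``width`` and
    ``height`` columns; one ``<source_id>.json`` report (and optional
    overlay PNG) is written per file, plus ``summary.csv``.  Per-file
    failures are logged and skipped; returns (n_ok, n_failed).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        with open(manifest, newline="") as fh:
            entries = list(csv.DictReader(fh))
        if not entries or not {"source_id", "width", "height"} <= set(entries[0]):
            raise CobbGeoError("manifest needs source_id, width, height columns")
    except OSError as exc:
        raise CobbGeoError(f"unreadable manifest: {exc}") from None

    rows = []
    n_failed = 0
    for entry in entries:
        source_id = entry["source_id"]
        t0 = time.perf_counter()
        try:
            ann = read_pose_labels(
                in_dir / f"{source_id}.txt",
                int(entry["width"]), int(entry["height"]),
                source_id=source_id,
            )
            report = measure(ann, cfg)
            (out_dir / f"{source_id}.json").write_text(report.to_json())
            if overlays:
                from .overlay import render_overlay

                render_overlay(report, ann, out_path=out_dir / f"{source_id}.png")
            primary = report.primary_curve()
            rows.append(
                {
                    "source_id": source_id,
                    "n_curves": len(report.curves),
                    "primary_cobb_deg": (
                        f"{primary.cobb_deg:.4f}" if primary else ""
                    ),
                    "severity": primary.severity.value if primary else "",
                    "pelvic_tilt_deg": (
                        f"{report.pelvic_tilt_deg:.4f}"
                        if report.pelvic_tilt_deg is not None
                        else ""
                    ),
                    "warnings": "|".join(report.warnings),
                }
            )
            logger.info(
                "measured %s in %.1f ms (%d warnings)",
                source_id, 1e3 * (time.perf_counter() - t0), len(report.warnings),
            )
        except (CobbGeoError, OSError, ValueError) as exc:
            n_failed += 1
            logger.warning("failed %s: %s", source_id, exc)

    summary = out_dir / "summary.csv"
    with summary.open("w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["source_id", "n_curves", "primary_cobb_deg",
                        "severity", "pelvic_tilt_deg", "warnings"],
        )
        writer.writeheader()
        writer.writerows(rows)
    return len(rows), n_failed
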