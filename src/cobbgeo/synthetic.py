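"""Parametric spine simulator with analytic ground truth.

The simulator emulates the keypoint annotations of a standing coronal
(PA) radiograph without synthesizing pixels.  A spine is a vertical
column of length ``column_length_px`` whose centerline deviates
laterally by a sum of Gaussian bumps

    x(s) = sum_k A_k * exp(-(s - mu_k)^2 / (2 * w_k^2)),   s in [0, 1],

with s running craniocaudally.  Vertebra n sits at equally spaced
arc-parameter s_n, modelled as a W_n x H_n rectangle whose endplates are
perpendicular to the local centerline tangent, i.e. both endplates are
inclined at

    phi_n = atan2(-x'(s_n), L)        (degrees, y-down frame),

so the true superior and inferior endplate angles coincide
(alpha_n = beta_n = phi_n) and every downstream angle is known in closed
form before any keypoint noise is applied.  The bilateral PSIS pair is
placed one vertebra-height caudal to the lowest vertebra and inclined at
the requested pelvic tilt.  Optional i.i.d. isotropic Gaussian jitter
(seeded) perturbs every keypoint; ground truth always refers to the
noiseless geometry.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .annotations import (
    BoundingBox,
    PelvisLandmarks,
    Point2D,
    SpineAnnotation,
    VertebraKeypoints,
    write_pose_labels,
)
from .errors import GenerationError
from .geometry import (
    CurveMeasurement,
    SearchConfig,
    VertebraAngles,
    decompose_curves,
)
from .labeling import LEVEL_NAMES

__all__ = [
    "GaussianBump",
    "SyntheticSpineSpec",
    "SpineGroundTruth",
    "generate_spine",
    "analytic_cobb",
    "truncate_fov",
    "spec_for_target_cobb",
    "simulate_cohort",
]

# Levels T1-T12 are thoracic; defaults below give height/width 0.9 for
# thoracic and 0.7 for lumbar vertebrae, the ratio ordering the
# aspect-ratio verification relies on.
_THORACIC_W, _THORACIC_H = 80.0, 72.0
_LUMBAR_W, _LUMBAR_H = 100.0, 70.0
_MARGIN_X = 160.0
_MARGIN_Y = 140.0


@dataclass(frozen=True)
class GaussianBump:
    """One lateral-deviation component of the centerline."""

    amplitude_px: float
    center: float  # s in [0, 1]
    width: float   # s-units


@dataclass(frozen=True)
class SyntheticSpineSpec:
    """Full parametric description of one synthetic spine."""

    n_vertebrae: int = 17
    bumps: tuple[GaussianBump, ...] = ()
    column_length_px: float = 1530.0
    pelvic_tilt_deg: float = 0.0
    include_pelvis: bool = True
    fov: str = "whole"
    noise_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_vertebrae <= 17):
            raise GenerationError("n_vertebrae must be in [1, 17]")
        if self.column_length_px <= 0:
            raise GenerationError("column length must be positive")
        if self.noise_sigma_px < 0:
            raise GenerationError("noise sigma must be >= 0")
        for b in self.bumps:
            if b.width <= 0:
                raise GenerationError("bump width must be positive")


@dataclass
class SpineGroundTruth:
    """Noiseless truth of a generated spine.

    ``phi`` plays the role of both endplate angles per vertebra; the true
    curves are obtained by the same admissible-pair search the
    measurement pipeline uses, applied to ``phi`` directly.
    """

    phi: list[float]
    levels: list[str]
    pelvic_tilt_deg: float | None
    curves: list[tuple[int, int, float]] = field(default_factory=list)

    def primary(self) -> tuple[int, int, float] | None:
        """Largest-magnitude true curve (tie: most cranial)."""
        if not self.curves:
            return None
        return max(self.curves, key=lambda c: (c[2], -c[0]))


def _deviation(spec: SyntheticSpineSpec, s: np.ndarray) -> np.ndarray:
    x = np.zeros_like(s)
    for b in spec.bumps:
        x += b.amplitude_px * np.exp(-((s - b.center) ** 2) / (2.0 * b.width**2))
    return x


def _deviation_slope(spec: SyntheticSpineSpec, s: np.ndarray) -> np.ndarray:
    dx = np.zeros_like(s)
    for b in spec.bumps:
        g = np.exp(-((s - b.center) ** 2) / (2.0 * b.width**2))
        dx += b.amplitude_px * g * (-(s - b.center) / b.width**2)
    return dx


def _phi_deg(spec: SyntheticSpineSpec) -> np.ndarray:
    """True endplate inclination per vertebra, degrees."""
    s = (np.arange(spec.n_vertebrae) + 0.5) / spec.n_vertebrae
    slope = _deviation_slope(spec, s)
    return np.degrees(np.arctan2(-slope, spec.column_length_px))


def _level_profile(spec: SyntheticSpineSpec) -> list[tuple[str, float, float]]:
    """(level, width, height) per generated vertebra, cranial to caudal."""
    n = spec.n_vertebrae
    if spec.include_pelvis:
        names = LEVEL_NAMES[len(LEVEL_NAMES) - n :]  # ends at L5
    else:
        names = LEVEL_NAMES[:n]  # starts at T1
    out = []
    for name in names:
        if name.startswith("T"):
            out.append((name, _THORACIC_W, _THORACIC_H))
        else:
            out.append((name, _LUMBAR_W, _LUMBAR_H))
    return out


def _rect_corners(
    cx: float, cy: float, w: float, h: float, phi_deg: float
) -> np.ndarray:
    """Corners (lt, rt, lb, rb) of a rotated rectangle, y-down frame."""
    r = math.radians(phi_deg)
    c, s = math.cos(r), math.sin(r)
    offs = np.array(
        [[-w / 2, -h / 2], [w / 2, -h / 2], [-w / 2, h / 2], [w / 2, h / 2]]
    )
    rot = offs @ np.array([[c, s], [-s, c]])  # (u,v) -> (uc - vs, us + vc)
    return rot + np.array([cx, cy])


def _rects_overlap(a: np.ndarray, b: np.ndarray) -> bool:
    """Separating-axis test for two convex quads given as 4x2 corner arrays."""
    for quad in (a, b):
        edges = [quad[1] - quad[0], quad[2] - quad[0]]
        for e in edges:
            axis = np.array([-e[1], e[0]])
            pa = a @ axis
            pb = b @ axis
            if pa.max() <= pb.min() or pb.max() <= pa.min():
                return False
    return True


def generate_spine(
    spec: SyntheticSpineSpec, cfg: SearchConfig = SearchConfig()
) -> tuple[SpineAnnotation, SpineGroundTruth]:
    """Generate one annotated spine and its analytic ground truth.

    The annotation carries pixel keypoints (jittered when
    ``spec.noise_sigma_px`` > 0); the ground truth is computed from the
    noiseless geometry and includes the true curves under ``cfg``.
    Raises :class:`GenerationError` when consecutive vertebra rectangles
    overlap (amplitude too extreme for the column length).
    """
    n = spec.n_vertebrae
    L = spec.column_length_px
    s = (np.arange(n) + 0.5) / n
    dev = _deviation(spec, s)
    phi = _phi_deg(spec)
    profile = _level_profile(spec)

    half_w = float(np.max(np.abs(dev))) + max(_THORACIC_W, _LUMBAR_W) + _MARGIN_X
    image_width = int(math.ceil(2 * half_w))
    x0 = image_width / 2.0
    y0 = _MARGIN_Y
    pelvis_drop = _LUMBAR_H + 60.0
    image_height = int(math.ceil(L + 2 * _MARGIN_Y + (pelvis_drop + 80.0)))

    if np.max(np.abs(phi)) > 60.0:
        raise GenerationError(
            "vertebral tilt exceeds 60 degrees; reduce bump amplitude"
        )

    centers = np.column_stack([x0 + dev, y0 + s * L])
    corner_sets = []
    for k in range(n):
        _, w, h = profile[k]
        corner_sets.append(_rect_corners(centers[k, 0], centers[k, 1], w, h, phi[k]))
    for k in range(n - 1):
        if _rects_overlap(corner_sets[k], corner_sets[k + 1]):
            raise GenerationError(
                "adjacent vertebrae overlap; reduce bump amplitude or widen bumps"
            )

    rng = np.random.default_rng(spec.seed)
    # one draw per possible keypoint so sigma scales a fixed jitter field
    jitter = spec.noise_sigma_px * rng.standard_normal((n, 5, 2))
    pelvis_jitter = spec.noise_sigma_px * rng.standard_normal((2, 2))

    vertebrae: list[VertebraKeypoints] = []
    for k in range(n):
        pts = np.vstack([corner_sets[k], centers[k]])  # lt, rt, lb, rb, sp
        pts = pts + jitter[k]
        lo = pts[:4].min(axis=0)
        hi = pts[:4].max(axis=0)
        bbox = BoundingBox(
            cx=float((lo[0] + hi[0]) / 2),
            cy=float((lo[1] + hi[1]) / 2),
            width=float(hi[0] - lo[0]),
            height=float(hi[1] - lo[1]),
        )
        vertebrae.append(
            VertebraKeypoints(
                lt=Point2D(*pts[0]), rt=Point2D(*pts[1]),
                lb=Point2D(*pts[2]), rb=Point2D(*pts[3]),
                sp=Point2D(*pts[4]), bbox=bbox,
            )
        )

    pelvis = None
    if spec.include_pelvis:
        t = math.radians(spec.pelvic_tilt_deg)
        sep = 2.0 * _LUMBAR_W
        py = centers[-1, 1] + pelvis_drop
        px = centers[-1, 0]
        left = np.array([px - sep / 2 * math.cos(t), py - sep / 2 * math.sin(t)])
        right = np.array([px + sep / 2 * math.cos(t), py + sep / 2 * math.sin(t)])
        left = left + pelvis_jitter[0]
        right = right + pelvis_jitter[1]
        lo = np.minimum(left, right) - 10.0
        hi = np.maximum(left, right) + 10.0
        pelvis = PelvisLandmarks(
            psis_left=Point2D(*left),
            psis_right=Point2D(*right),
            bbox=BoundingBox(
                cx=float((lo[0] + hi[0]) / 2), cy=float((lo[1] + hi[1]) / 2),
                width=float(hi[0] - lo[0]), height=float(hi[1] - lo[1]),
            ),
        )

    ann = SpineAnnotation(
        vertebrae=vertebrae,
        pelvis=pelvis,
        image_width=image_width,
        image_height=image_height,
        fov=spec.fov,
        source_id=f"synthetic-{spec.seed}",
    ).sorted()

    gt = SpineGroundTruth(
        phi=[float(p) for p in phi],
        levels=[name for name, _, _ in profile],
        pelvic_tilt_deg=spec.pelvic_tilt_deg if spec.include_pelvis else None,
    )
    gt.curves = analytic_cobb(gt, cfg)
    return ann, gt


def analytic_cobb(
    gt: SpineGroundTruth, cfg: SearchConfig = SearchConfig()
) -> list[tuple[int, int, float]]:
    """True curves from phi alone, same search semantics as the pipeline."""
    angles = [
        VertebraAngles(alpha=p, beta=p, theta=p, index=i)
        for i, p in enumerate(gt.phi)
    ]
    return [(c.upper_idx, c.lower_idx, c.cobb_deg)
            for c in decompose_curves(angles, cfg)]


def truncate_fov(
    ann: SpineAnnotation,
    gt: SpineGroundTruth,
    mode: str,
    cfg: SearchConfig = SearchConfig(),
) -> tuple[SpineAnnotation, SpineGroundTruth]:
    """Crop a whole-spine pair to a thoracic (T1-T12) or lumbar
    (T10-L5 + pelvis) window with a consistently restricted ground truth.
    """
    if mode not in ("thoracic", "lumbar"):
        raise GenerationError(f"unknown FOV mode {mode!r}")
    keep_levels = (
        {f"T{i}" for i in range(1, 13)}
        if mode == "thoracic"
        else {f"T{i}" for i in (10, 11, 12)} | {f"L{i}" for i in range(1, 6)}
    )
    idx = [i for i, lvl in enumerate(gt.levels) if lvl in keep_levels]
    if not idx:
        raise GenerationError(f"no vertebrae available for {mode} window")
    if mode == "lumbar" and ann.pelvis is None:
        raise GenerationError("lumbar window requires a pelvis")

    sub_ann = replace(
        ann,
        vertebrae=[ann.vertebrae[i] for i in idx],
        pelvis=ann.pelvis if mode == "lumbar" else None,
        fov=mode,
    )
    sub_gt = SpineGroundTruth(
        phi=[gt.phi[i] for i in idx],
        levels=[gt.levels[i] for i in idx],
        pelvic_tilt_deg=gt.pelvic_tilt_deg if mode == "lumbar" else None,
    )
    sub_gt.curves = analytic_cobb(sub_gt, cfg)
    return sub_ann, sub_gt


def _primary_magnitude(phi: np.ndarray, cfg: SearchConfig) -> float:
    """Max admissible-pair |phi_i - phi_j| ignoring the reporting threshold."""
    n = len(phi)
    best = 0.0
    for i in range(n):
        for j in range(i + cfg.min_span, n):
            d = abs(phi[i] - phi[j])
            d = 180.0 - d if d > 90.0 else d
            best = max(best, d)
    return best


def spec_for_target_cobb(
    target_deg: float,
    rng: np.random.Generator | int = 0,
    *,
    n_vertebrae: int = 17,
    pelvic_tilt_deg: float | None = None,
    noise_sigma_px: float = 0.0,
    cfg: SearchConfig = SearchConfig(),
) -> SyntheticSpineSpec:
    """Single-bump spec whose true primary Cobb equals ``target_deg``.

    Samples the bump center in U(0.35, 0.65) and width in U(0.12, 0.20)
    of the column, then solves for the amplitude by bisection so the
    admissible-pair search over the analytic phi hits the target exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not 0 < target_deg < 90:
        raise GenerationError("target Cobb must be in (0, 90) degrees")
    center = float(rng.uniform(0.35, 0.65))
    width = float(rng.uniform(0.12, 0.20))
    tilt = float(rng.uniform(-8.0, 8.0)) if pelvic_tilt_deg is None else pelvic_tilt_deg
    seed = int(rng.integers(0, 2**31 - 1))

    def make(amp: float) -> SyntheticSpineSpec:
        return SyntheticSpineSpec(
            n_vertebrae=n_vertebrae,
            bumps=(GaussianBump(amp, center, width),),
            pelvic_tilt_deg=tilt,
            noise_sigma_px=noise_sigma_px,
            seed=seed,
        )

    def f(amp: float) -> float:
        return _primary_magnitude(_phi_deg(make(amp)), cfg) - target_deg

    hi = 50.0
    while f(hi) < 0 and hi < 1e5:
        hi *= 2.0
    if f(hi) < 0:
        raise GenerationError("target Cobb unreachable for sampled bump shape")
    amp = brentq(f, 0.0, hi, xtol=1e-10)
    return make(float(amp))


def simulate_cohort(
    n: int,
    out_dir: str | Path,
    *,
    noise_sigma_px: float = 0.0,
    seed: int = 0,
    fov: str = "whole",
    cobb_range: tuple[float, float] = (5.0, 58.0),
    cfg: SearchConfig = SearchConfig(),
) -> Path:
    """Write ``n`` simulated annotations plus a ground-truth CSV.

    Each case is a single-bump spine with a true primary Cobb drawn
    uniformly from ``cobb_range``.  Returns the path of the ground-truth
    CSV (columns: source_id, width, height, true_primary_cobb,
    upper_idx, lower_idx, pelvic_tilt).  The same CSV doubles as the
    image-size manifest for batch measurement.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        target = float(rng.uniform(*cobb_range))
        spec = spec_for_target_cobb(target, rng, noise_sigma_px=noise_sigma_px, cfg=cfg)
        ann, gt = generate_spine(spec, cfg)
        if fov in ("thoracic", "lumbar"):
            ann, gt = truncate_fov(ann, gt, fov, cfg)
        source_id = f"case_{k:04d}"
        ann.source_id = source_id
        write_pose_labels(ann, out / f"{source_id}.txt")
        primary = gt.primary()
        rows.append(
            {
                "source_id": source_id,
                "width": ann.image_width,
                "height": ann.image_height,
                "true_primary_cobb": f"{primary[2]:.6f}" if primary else "",
                "upper_idx": primary[0] if primary else "",
                "lower_idx": primary[1] if primary else "",
                "pelvic_tilt": (
                    f"{gt.pelvic_tilt_deg:.6f}" if gt.pelvic_tilt_deg is not None else ""
                ),
            }
        )
    manifest = out / "ground_truth.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
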