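import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobbgeo.annotations import Point2D, SpineAnnotation
from cobbgeo.errors import CobbGeoError, DegenerateVertebraError
from cobbgeo.geometry import (
    SearchConfig,
    Severity,
    angles_from_annotation,
    bilateral_tilt,
    classify_severity,
    cobb_pair,
    decompose_curves,
    endplate_angles,
    find_end_vertebrae,
    normalize_angle,
    vertebral_tilt,
)
from cobbgeo.synthetic import SyntheticSpineSpec, generate_spine, spec_for_target_cobb

from conftest import angles_from_tilts, brute_force_end_vertebrae


@pytest.mark.parametrize(
    "raw, expected",
    [(0, 0), (135, -45), (90, -90), (-90, -90), (45, 45), (180, 0),
     (-135, 45), (270, -90), (89.999, 89.999)],
)
def test_normalize_angle_maps_to_half_open_interval(raw, expected):
    out = normalize_angle(raw)
    assert out == pytest.approx(expected, abs=1e-12)
    assert -90 <= out < 90
    # congruent mod 180
    assert (out - raw) % 180 == pytest.approx(0, abs=1e-9)


@settings(max_examples=200, derandomize=True)
@given(st.floats(-1e6, 1e6), st.integers(-20, 20))
def test_normalize_angle_idempotent_and_period_180(raw, k):
    out = normalize_angle(raw)
    assert -90 <= out < 90
    assert normalize_angle(out) == out
    assert normalize_angle(raw + 180.0 * k) == pytest.approx(out, abs=1e-6)


@settings(max_examples=200, derandomize=True)
@given(st.floats(-90, 89.999), st.floats(-90, 89.999))
def test_cobb_pair_magnitude_symmetric_and_acute(a, b):
    c = cobb_pair(a, b)
    assert 0 <= c <= 90
    assert cobb_pair(b, a) == pytest.approx(c, abs=1e-9)


def test_normalize_angle_rejects_non_finite():
    with pytest.raises(CobbGeoError):
        normalize_angle(math.nan)


def _vertebra_from_corners(lt, rt, lb, rb):
    from cobbgeo.annotations import BoundingBox, VertebraKeypoints

    xs = [p[0] for p in (lt, rt, lb, rb)]
    ys = [p[1] for p in (lt, rt, lb, rb)]
    return VertebraKeypoints(
        lt=Point2D(*lt), rt=Point2D(*rt), lb=Point2D(*lb), rb=Point2D(*rb),
        sp=Point2D(sum(xs) / 4, sum(ys) / 4),
        bbox=BoundingBox(
            (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2,
            max(xs) - min(xs) or 1.0, max(ys) - min(ys) or 1.0,
        ),
    )


class TestEndplateAngles:
    def test_horizontal_endplates_are_zero(self):
        v = _vertebra_from_corners((0, 0), (10, 0), (0, 8), (10, 8))
        assert endplate_angles(v) == (0.0, 0.0)

    def test_45_degree_superior_endplate(self):
        v = _vertebra_from_corners((0, 0), (10, 10), (0, 12), (10, 20))
        alpha, _ = endplate_angles(v)
        assert alpha == pytest.approx(45.0)

    def test_vertical_segment_normalizes_to_minus_90(self):
        v = _vertebra_from_corners((0, 0), (0, 5), (0, 12), (10, 12))
        alpha, _ = endplate_angles(v)
        assert alpha == -90.0

    def test_coincident_corners_raise_degenerate(self):
        v = _vertebra_from_corners((5, 5), (5, 5), (0, 12), (10, 12))
        with pytest.raises(DegenerateVertebraError):
            endplate_angles(v)

    def test_positive_angle_means_right_end_inferior(self):
        # y grows downward: right corner lower on the image -> positive
        v = _vertebra_from_corners((0, 0), (10, 2), (0, 10), (10, 12))
        alpha, beta = endplate_angles(v)
        assert alpha > 0 and beta > 0


@pytest.mark.parametrize("a, b, expected", [(0, 0, 0), (10, 20, 15), (-8, 8, 0)])
def test_vertebral_tilt_is_arithmetic_mean(a, b, expected):
    assert vertebral_tilt(a, b) == expected


class TestCobbPair:
    @pytest.mark.parametrize(
        "a, b, expected", [(10, -10, 20), (3, 3, 0), (-45.5, -45.5, 0), (85, -85, 10)]
    )
    def test_examples(self, a, b, expected):
        assert cobb_pair(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(-90, 90, size=(200, 2)):
            c = cobb_pair(a, b)
            assert c == pytest.approx(cobb_pair(b, a), abs=1e-12)
            assert 0 <= c <= 90


class TestEndVertebraSearch:
    def test_worked_sequence_finds_3_7_pair(self):
        angles = angles_from_tilts([-1, 3, 9, 14, 7, 2, -1, -2])
        c = find_end_vertebrae(angles, cfg=SearchConfig(min_span=3, min_angle=5))
        assert (c.upper_idx, c.lower_idx) == (3, 7)
        assert c.cobb_deg == pytest.approx(16.0)

    def test_below_threshold_returns_none(self):
        angles = angles_from_tilts([0, 1, 2, 1, 0])
        assert find_end_vertebrae(angles) is None

    def test_interval_shorter_than_span_returns_none(self):
        angles = angles_from_tilts([0, 20, -20])
        assert find_end_vertebrae(angles, cfg=SearchConfig(min_span=3)) is None

    def test_skipped_vertebrae_excluded_but_interval_not_split(self):
        tilts = [-1, 3, 9, 14, 7, 2, -1, -2]
        angles = angles_from_tilts(tilts)
        angles[3] = None  # best upper end missing -> next best pair wins
        got = find_end_vertebrae(angles)
        # exhaustive check over the remaining indices
        best = None
        for i in range(8):
            for j in range(i + 3, 8):
                if 3 in (i, j):
                    continue
                c = abs(tilts[i] - tilts[j])
                if best is None or c > best[0]:
                    best = (c, i, j)
        assert got is not None
        assert (got.upper_idx, got.lower_idx) == (best[1], best[2])
        assert got.cobb_deg == pytest.approx(best[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(4, 18))
            tilts = rng.uniform(-30, 30, n)
            angles = angles_from_tilts(tilts)
            got = find_end_vertebrae(angles)
            want = brute_force_end_vertebrae(tilts, tilts, 0, n - 1, 3, 5.0)
            if want is None:
                assert got is None
            else:
                assert (got.upper_idx, got.lower_idx) == (want[0], want[1])
                assert got.cobb_deg == pytest.approx(want[2], abs=1e-12)

    def test_tie_break_prefers_lexicographically_smallest_pair(self):
        # two pairs with identical C: (0,3) and (1,4) both give 10
        angles = angles_from_tilts([5, 5, 0, -5, -5])
        c = find_end_vertebrae(angles)
        assert (c.upper_idx, c.lower_idx) == (0, 3)


class TestDecomposeCurves:
    def test_worked_triple_curve_sequence(self):
        angles = angles_from_tilts([0, 0, 5, 12, 6, 0, -6, -12, -5, 0, 0, 0])
        curves = decompose_curves(angles)
        got = [(c.upper_idx, c.lower_idx, c.cobb_deg) for c in curves]
        assert got == [(0, 3, 12.0), (3, 7, 24.0), (7, 10, 12.0)]

    def test_straight_spine_yields_no_curves(self):
        assert decompose_curves(angles_from_tilts([0.0] * 12)) == []

    def test_single_c_curve(self):
        curves = decompose_curves(angles_from_tilts([0, 4, 10, 4, 0, 0, 0, 0]))
        assert len(curves) == 1

    def test_curve_interiors_never_overlap_and_cap_respected(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 18))
            curves = decompose_curves(angles_from_tilts(rng.uniform(-40, 40, n)))
            assert len(curves) <= 3
            for a, b in zip(curves, curves[1:]):
                assert a.lower_idx <= b.upper_idx  # shared endpoint allowed

    def test_max_curves_cap_keeps_larger_flank(self):
        angles = angles_from_tilts([0, 0, 5, 12, 6, 0, -6, -12, -5, 0, 0, 0])
        curves = decompose_curves(angles, SearchConfig(max_curves=2))
        assert len(curves) == 2
        assert (curves[0].upper_idx, curves[0].lower_idx) == (0, 3)  # tie -> cranial
        assert curves[1].cobb_deg == pytest.approx(24.0)


class TestBilateralTilt:
    def test_level_pair_is_zero(self):
        assert bilateral_tilt(Point2D(0, 0), Point2D(100, 0)) == 0.0

    def test_right_point_inferior_is_positive(self):
        assert bilateral_tilt(Point2D(0, 0), Point2D(100, 10)) == pytest.approx(
            5.7106, abs=1e-4
        )

    def test_mirror_negates(self):
        t = bilateral_tilt(Point2D(0, 0), Point2D(100, 10))
        # reflect about a vertical axis and swap to restore x-order
        t_m = bilateral_tilt(Point2D(100, 10), Point2D(200, 0))
        assert t_m == pytest.approx(-t, abs=1e-12)

    def test_rejects_unordered_or_coincident(self):
        with pytest.raises(CobbGeoError):
            bilateral_tilt(Point2D(5, 0), Point2D(5, 0))


@pytest.mark.parametrize(
    "cobb, expected",
    [
        (8, Severity.SUB_THRESHOLD), (10, Severity.SUB_THRESHOLD),
        (10.01, Severity.MILD), (15, Severity.MILD), (19.99, Severity.MILD),
        (20, Severity.MODERATE), (35, Severity.MODERATE),
        (35.01, Severity.SEVERE), (40, Severity.SEVERE),
    ],
)
def test_severity_strata_boundaries(cobb, expected):
    assert classify_severity(cobb) is expected


def test_severity_rejects_negative():
    with pytest.raises(CobbGeoError):
        classify_severity(-1.0)


# ---------------------------------------------------------------------------
# geometric invariances of the whole measurement chain
# ---------------------------------------------------------------------------

def _transform(ann: SpineAnnotation, fn) -> SpineAnnotation:
    from cobbgeo.annotations import BoundingBox, VertebraKeypoints

    def tp(p: Point2D) -> Point2D:
        return Point2D(*fn(p.x, p.y))

    new_verts = []
    for v in ann.vertebrae:
        pts = {k: tp(getattr(v, k)) for k in ("lt", "rt", "lb", "rb", "sp")}
        # re-establish image x-order after a mirror
        if pts["lt"].x > pts["rt"].x:
            pts["lt"], pts["rt"] = pts["rt"], pts["lt"]
        if pts["lb"].x > pts["rb"].x:
            pts["lb"], pts["rb"] = pts["rb"], pts["lb"]
        xs = [p.x for p in pts.values()]
        ys = [p.y for p in pts.values()]
        new_verts.append(
            VertebraKeypoints(
                **pts,
                bbox=BoundingBox(
                    (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2,
                    max(xs) - min(xs), max(ys) - min(ys),
                ),
            )
        )
    return replace(ann, vertebrae=new_verts, pelvis=None)


def _all_angles(ann):
    recs = angles_from_annotation(ann)
    return np.array([[r.alpha, r.beta, r.theta] for r in recs])


def _cobbs(ann):
    return [c.cobb_deg for c in decompose_curves(angles_from_annotation(ann))]


@pytest.fixture(scope="module")
def random_spines():
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(20):
        spec = spec_for_target_cobb(float(rng.uniform(6, 45)), rng)
        out.append(generate_spine(spec)[0])
    return out


def test_translation_and_scale_invariance(random_spines):
    for ann in random_spines:
        base_angles = _all_angles(ann)
        base_cobbs = _cobbs(ann)
        shifted = _transform(ann, lambda x, y: (x + 137.0, y - 52.5))
        scaled = _transform(ann, lambda x, y: (2.75 * x, 2.75 * y))
        for other in (shifted, scaled):
            assert np.allclose(_all_angles(other), base_angles, atol=1e-9)
            assert np.allclose(_cobbs(other), base_cobbs, atol=1e-9)


def test_rotation_shifts_endplate_angles_and_preserves_cobb(random_spines):
    rng = np.random.default_rng(5)
    for ann in random_spines:
        base_angles = _all_angles(ann)
        base_cobbs = _cobbs(ann)
        delta = float(rng.uniform(-10, 10))
        r = math.radians(delta)
        cx, cy = 500.0, 800.0

        def rot(x, y, r=r, cx=cx, cy=cy):
            dx, dy = x - cx, y - cy
            return (
                cx + dx * math.cos(r) - dy * math.sin(r),
                cy + dx * math.sin(r) + dy * math.cos(r),
            )

        rotated = _transform(ann, rot)
        got = _all_angles(rotated)
        assert np.allclose(got[:, :2], base_angles[:, :2] + delta, atol=1e-9)
        assert np.allclose(_cobbs(rotated), base_cobbs, atol=1e-9)


def test_mirror_negates_tilts_and_preserves_cobb(random_spines):
    for ann in random_spines:
        base_angles = _all_angles(ann)
        base_cobbs = _cobbs(ann)
        mirrored = _transform(ann, lambda x, y: (ann.image_width - x, y))
        assert np.allclose(_all_angles(mirrored), -base_angles, atol=1e-9)
        assert np.allclose(_cobbs(mirrored), base_cobbs, atol=1e-9)
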