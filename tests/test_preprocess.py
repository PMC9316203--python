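import numpy as np
import pytest

from stylemorph.outlines import Outline, OutlineError
from stylemorph.preprocess import (
    HalfOutline,
    detect_landmarks,
    mirror_half,
    resample_equal_arclength,
    straighten_stylet,
)
from stylemorph.synthetic import ShapeParams, generate_half_outline

from helpers import circle_outline


@pytest.fixture
def half():
    return generate_half_outline(ShapeParams(tooth_count=2))


def _landmark_angle(h: HalfOutline) -> float:
    """Angle of the proximal->distal landmark segment from the +y axis."""
    v = h.points[h.distal] - h.points[h.proximal]
    return np.arctan2(v[0], v[1])


class TestStraightenStylet:
    def test_idempotent_once_straightened(self, half):
        once = straighten_stylet(half)
        twice = straighten_stylet(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)

    def test_perpendicular_landmark_rotated_90_tip_anterior(self, half):
        bent = generate_half_outline(ShapeParams(tooth_count=2), bend_angle=np.pi / 2)
        # bending is applied relative to the raw (unstraightened) pose
        assert abs(abs(_landmark_angle(bent) - _landmark_angle(half)) - np.pi / 2) < 1e-9
        fixed = straighten_stylet(bent)
        assert abs(_landmark_angle(fixed)) < 1e-10
        assert fixed.points[fixed.distal][1] > fixed.points[fixed.proximal][1]

    def test_random_bends_always_straightened(self, half):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            bent = straighten_stylet(half)  # start from canonical pose
            ang = rng.uniform(-2.5, 2.5)
            prox = bent.points[bent.proximal]
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s], [s, c]])
            pts = bent.points.copy()
            lo, hi = bent.stylet_start, bent.proximal
            pts[lo : hi + 1] = (pts[lo : hi + 1] - prox) @ rot.T + prox
            rebent = HalfOutline(pts, bent.side, bent.proximal, bent.distal,
                                 stylet_start=bent.stylet_start)
            assert abs(_landmark_angle(straighten_stylet(rebent))) < 1e-10

    def test_isometry_on_blade(self, half):
        bent = generate_half_outline(ShapeParams(tooth_count=2), bend_angle=0.7)
        fixed = straighten_stylet(bent)
        lo, hi = bent.stylet_start, bent.proximal
        blade0 = bent.points[lo : hi + 1]
        blade1 = fixed.points[lo : hi + 1]
        d0 = np.linalg.norm(blade0[:, None] - blade0[None, :], axis=2)
        d1 = np.linalg.norm(blade1[:, None] - blade1[None, :], axis=2)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_points_outside_blade_untouched(self, half):
        bent = generate_half_outline(ShapeParams(tooth_count=2), bend_angle=0.5)
        fixed = straighten_stylet(bent)
        lo, hi = bent.stylet_start, bent.proximal
        np.testing.assert_array_equal(fixed.points[:lo], bent.points[:lo])
        np.testing.assert_array_equal(fixed.points[hi + 1 :], bent.points[hi + 1 :])

    def test_coincident_landmarks_rejected(self):
        pts = np.array([[0, 0], [1, 0.5], [1, 1], [0.5, 1.5], [0, 2]], float)
        h = HalfOutline(pts, "right", proximal=1, distal=1.0 and 2, stylet_start=1)
        h.points[2] = h.points[1]
        with pytest.raises(OutlineError, match="coincident"):
            straighten_stylet(h)


class TestMirrorHalf:
    def test_semicircle_becomes_full_circle(self):
        t = np.linspace(-np.pi / 2, np.pi / 2, 200)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        pts[0, 0] = pts[-1, 0] = 0.0
        h = HalfOutline(pts, "right", proximal=10, distal=20)
        full = mirror_half(h)
        assert full.area == pytest.approx(np.pi, rel=1e-3)

    def test_output_mirror_symmetric(self, half):
        full = mirror_half(half)
        pts = full.points
        mirrored = pts * np.array([-1.0, 1.0])
        dists = np.min(
            np.linalg.norm(pts[:, None, :] - mirrored[None, :, :], axis=2), axis=1
        )
        assert dists.max() < 1e-9

    def test_point_count(self, half):
        n_half = len(half.points)
        full = mirror_half(half)
        assert full.n_points == 2 * (n_half - 2) + 2

    def test_counterclockwise(self, half):
        assert mirror_half(half).area > 0

    def test_self_intersection_reported_with_segments(self):
        # a half that pokes across the midline after mirroring
        pts = np.array(
            [[0.0, 0.0], [1.0, 0.5], [-0.4, 1.0], [1.0, 1.5], [0.0, 2.0]]
        )
        h = HalfOutline(pts, "right", proximal=1, distal=2)
        with pytest.raises(OutlineError, match="segments"):
            mirror_half(h)


class TestResample:
    def test_circle_equal_chords(self):
        # dense polygon approximation of the circle so vertex-quantization
        # effects sit below the assertion tolerance
        out = resample_equal_arclength(circle_outline(60_000), 256)
        chords = np.linalg.norm(np.diff(out.closed_points(), axis=0), axis=1)
        assert chords.max() - chords.min() < 1e-9

    def test_idempotent(self, head_outlines):
        o = head_outlines[0]
        once = resample_equal_arclength(o, 256)
        twice = resample_equal_arclength(once, 256)
        scale = o.perimeter()
        assert np.abs(twice.points - once.points).max() < 1e-6 * scale

    def test_square_perimeter_preserved(self):
        sq = Outline("sq", np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        out = resample_equal_arclength(sq, 400)
        assert out.perimeter() == pytest.approx(4.0, abs=1e-6)

    def test_starts_at_anterior_pole(self, head_outlines):
        for o in head_outlines:
            res = resample_equal_arclength(o, 128)
            x0, y0 = res.points[0]
            assert abs(x0) < 1e-9
            # the topmost midline crossing is the head's anterior pole (the
            # stylet tips lie off-midline), at y = head_length = 1
            assert y0 == pytest.approx(1.0, abs=1e-3)

    def test_m_below_64_rejected(self):
        with pytest.raises(ValueError, match=">= 64"):
            resample_equal_arclength(circle_outline(100), 32)


class TestLandmarkDetection:
    def test_detects_near_generator_truth(self):
        h = generate_half_outline(ShapeParams())
        det = detect_landmarks(h)
        prox_truth = h.points[h.proximal]
        prox_det = det.points[det.proximal]
        assert np.linalg.norm(prox_det - prox_truth) < 0.1  # within a blade width
        assert det.distal < det.proximal
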