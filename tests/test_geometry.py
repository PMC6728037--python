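"""Chord measurement: oracle equivalence, invariances, ellipse fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from bladdervol.frames import Chord, NoBladderDetected
from bladdervol.geometry import (
    contour_points,
    fit_ellipse,
    longest_chord,
    measure_longitudinal,
    measure_transverse,
    postprocess_mask,
)

from .oracles import brute_force_longest_chord


def ellipse_mask(shape, center, semi_axes_px, rotation_deg=0.0):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(*center, *semi_axes_px, shape=shape, rotation=np.deg2rad(rotation_deg))
    mask[rr, cc] = True
    return mask


def assert_matches_oracle(mask, spacing, constraint=None):
    chord = longest_chord(mask, spacing, angle_constraint=constraint)
    oracle = brute_force_longest_chord(mask, spacing, angle_constraint=constraint)
    assert (chord.p0, chord.p1) == (oracle[0], oracle[1])
    assert chord.length_mm == oracle[2]
    assert chord.angle_deg == oracle[3]


class TestPostprocess:
    def test_keeps_largest_component(self):
        mask = np.zeros((80, 80), dtype=bool)
        mask[5:45, 5:45] = True  # 1600 px
        mask[60:64, 60:64] = True  # 16 px
        out = postprocess_mask(mask)
        assert out[20, 20] and not out[61, 61]

    def test_idempotent_on_solid_disc(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw_disk((30, 30), 20)
        mask[rr, cc] = True
        assert np.array_equal(postprocess_mask(mask), mask)

    def test_fills_interior_hole(self):
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = draw_disk((30, 30), 20)
        mask[rr, cc] = True
        solid_area = mask.sum()
        holey = mask.copy()
        holey[28:33, 28:33] = False
        assert postprocess_mask(holey).sum() == solid_area

    def test_empty_stays_empty(self):
        out = postprocess_mask(np.zeros((10, 10), dtype=bool))
        assert not out.any()


class TestLongestChord:
    def test_circle_diameter_any_constraint(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = draw_disk((100, 100), 80)
        mask[rr, cc] = True
        for constraint in (None, (0.0, 10.0), (45.0, 10.0)):
            chord = longest_chord(mask, 0.25, angle_constraint=constraint)
            assert abs(chord.length_mm - 40.0) <= 2 * 0.25

    def test_axis_aligned_ellipse_horizontal_constraint(self):
        mask = ellipse_mask((120, 260), (60, 130), (40, 100))
        chord = longest_chord(mask, 0.5, angle_constraint=(0.0, 10.0))
        assert abs(chord.length_mm - 200 * 0.5) <= 2 * 0.5
        assert_matches_oracle(mask[::2, ::2], 1.0, (0.0, 10.0))

    def test_rotated_ellipse_unconstrained_recovers_major_axis(self):
        mask = ellipse_mask((240, 260), (120, 130), (40, 100), rotation_deg=30.0)
        chord = longest_chord(mask, 0.5)
        assert abs(chord.length_mm - 200 * 0.5) <= 2 * 0.5
        # skimage draws its rotation counterclockwise in (row, col) math
        # coords, which is 180 - rot in screen orientation
        assert abs(chord.angle_deg - 150.0) <= 2.0

    def test_empty_mask_raises(self):
        with pytest.raises(NoBladderDetected):
            longest_chord(np.zeros((10, 10), dtype=bool), 0.5)

    def test_impossible_constraint_raises(self):
        mask = np.zeros((5, 30), dtype=bool)
        mask[2, 2:28] = True  # horizontal line: no vertical pair exists
        with pytest.raises(ValueError):
            longest_chord(mask, 0.5, angle_constraint=(90.0, 1.0))

    def test_scale_equivariance(self):
        mask = ellipse_mask((100, 120), (50, 60), (30, 45), rotation_deg=15.0)
        c1 = longest_chord(mask, 0.3)
        c2 = longest_chord(mask, 0.6)
        assert c2.length_mm == pytest.approx(2 * c1.length_mm, rel=1e-12)
        assert (c1.p0, c1.p1) == (c2.p0, c2.p1)

    def test_anisotropic_spacing_lengths_in_mm(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10, 10:31] = True
        mask[10:31, 10] = True
        chord = longest_chord(mask, (1.0, 2.0))  # rows 1 mm, cols 2 mm
        # the horizontal arm is physically longer under anisotropic spacing
        assert chord.length_mm >= 40.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((28, 28), dtype=bool)
        for _ in range(rng.integers(1, 4)):
            rr, cc = draw_disk(tuple(rng.integers(6, 22, size=2)), rng.integers(3, 8), shape=mask.shape)
            mask[rr, cc] = True
        mask = postprocess_mask(mask)
        constraint = None if seed % 2 == 0 else (float(rng.uniform(0, 180)), 15.0)
        try:
            chord = longest_chord(mask, 0.5, angle_constraint=constraint)
        except ValueError:
            assert brute_force_longest_chord(mask, 0.5, constraint) is None
            return
        oracle = brute_force_longest_chord(mask, 0.5, constraint)
        assert (chord.p0, chord.p1, chord.length_mm, chord.angle_deg) == oracle


class TestRotationConsistency:
    @pytest.mark.parametrize("rotation", [0.0, 20.0, 45.0, 70.0])
    def test_unconstrained_b_invariant_under_rotation(self, rotation):
        mask = ellipse_mask((240, 240), (120, 120), (40, 90), rotation_deg=rotation)
        chord = longest_chord(mask, 0.5)
        assert abs(chord.length_mm - 180 * 0.5) <= 2 * 0.5


class TestSectionMeasurements:
    def test_transverse_circle(self):
        mask = np.zeros((160, 160), dtype=bool)
        rr, cc = draw_disk((80, 80), 60)
        mask[rr, cc] = True
        a_cm, chord = measure_transverse(mask, 0.5)
        assert a_cm == pytest.approx(6.0, abs=2 * 0.05)
        assert isinstance(chord, Chord)

    def test_longitudinal_rotated_ellipse(self):
        mask = ellipse_mask((260, 260), (130, 130), (40, 100), rotation_deg=20.0)
        b_cm, c_cm, _ = measure_longitudinal(mask, 0.5)
        assert b_cm == pytest.approx(200 * 0.05, abs=2 * 0.05)
        assert c_cm == pytest.approx(80 * 0.05, abs=2 * 0.05)
        assert b_cm >= c_cm

    def test_longitudinal_circle_b_equals_c(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = draw_disk((100, 100), 70)
        mask[rr, cc] = True
        b_cm, c_cm, _ = measure_longitudinal(mask, 0.4)
        assert b_cm == pytest.approx(c_cm, abs=2 * 0.04)

    def test_degenerate_line_segment(self):
        mask = np.zeros((8, 60), dtype=bool)
        mask[4, 5:55] = True
        b_cm, c_cm, _ = measure_longitudinal(mask, 0.5)
        assert b_cm == pytest.approx(49 * 0.05, abs=0.05)
        assert c_cm <= 0.05 * np.sqrt(2)

    def test_b_at_least_c_on_random_shapes(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = ellipse_mask(
                (120, 120),
                (60, 60),
                (rng.integers(10, 40), rng.integers(10, 40)),
                rotation_deg=rng.uniform(0, 180),
            )
            b_cm, c_cm, _ = measure_longitudinal(mask, 0.5)
            assert b_cm >= c_cm


class TestFitEllipse:
    def test_recovers_axes_of_exact_ellipse(self):
        mask = ellipse_mask((260, 260), (130, 130), (40, 100), rotation_deg=25.0)
        major_cm, minor_cm, angle = fit_ellipse(mask, 0.5)
        assert major_cm == pytest.approx(10.0, rel=0.02)
        assert minor_cm == pytest.approx(4.0, rel=0.02)
        assert abs(angle - 155.0) < 4.0  # drawn rotation appears as 180 - rot

    def test_circle_major_equals_minor(self):
        mask = np.zeros((200, 200), dtype=bool)
        rr, cc = draw_disk((100, 100), 75)
        mask[rr, cc] = True
        major_cm, minor_cm, _ = fit_ellipse(mask, 0.4)
        assert major_cm == pytest.approx(minor_cm, rel=0.02)

    def test_chord_and_ellipse_modes_agree_on_exact_ellipses(self):
        for rot in (0.0, 15.0, 40.0):
            mask = ellipse_mask((260, 260), (130, 130), (50, 90), rotation_deg=rot)
            b_cm, c_cm, _ = measure_longitudinal(mask, 0.5)
            major_cm, minor_cm, _ = fit_ellipse(mask, 0.5)
            assert b_cm == pytest.approx(major_cm, rel=0.03)
            assert c_cm == pytest.approx(minor_cm, rel=0.03)

    def test_collinear_contour_rejected(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 5:35] = True
        with pytest.raises(ValueError):
            fit_ellipse(mask, 0.5)
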