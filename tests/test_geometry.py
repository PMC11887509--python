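"""Construction lines, heights and inclinations against closed-form oracles."""

import math

import numpy as np
import pytest

from faceharmony.errors import DegenerateGeometryError, MissingLandmarkError
from faceharmony.geometry import (
    Line,
    construct_nfl,
    construct_val,
    measure_heights,
    measure_inclinations,
    measure_profile,
    signed_angle_deg,
)
from faceharmony.landmarks import LandmarkSet, calibrate_scale

from conftest import oracle_profile, random_profiles


class TestCalibrateScale:
    @pytest.mark.parametrize(
        "p1, p2, known_mm, expected",
        [((0, 0), (0, 100), 50, 0.5), ((0, 0), (3, 4), 5, 1.0)],
    )
    def test_known_segments(self, p1, p2, known_mm, expected):
        assert calibrate_scale(p1, p2, known_mm) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_explicit_distance_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p1, p2 = rng.uniform(-100, 100, (2, 2))
            mm = rng.uniform(10, 100)
            d = math.sqrt((p2[0] - p1[0]) ** 2 + (p2[1] - p1[1]) ** 2)
            assert calibrate_scale(p1, p2, mm) == pytest.approx(mm / d, abs=1e-12)
            # applying the factor to the segment recovers the known length
            assert calibrate_scale(p1, p2, mm) * d == pytest.approx(mm, rel=1e-12)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            calibrate_scale((1, 2), (1, 2), 10)


class TestNasofrontalLine:
    def test_vertical_case(self):
        ls = LandmarkSet.from_coords("s", {"G": (0, 100), "N": (0, 50)})
        nfl = construct_nfl(ls)
        assert np.allclose(nfl.anchor, [0, 50])
        assert np.allclose(nfl.direction, [0, -1])

    def test_two_point_direction(self):
        ls = LandmarkSet.from_coords("s", {"G": (10, 100), "N": (0, 50)})
        d = construct_nfl(ls).direction
        expect = np.array([-10.0, -50.0]) / np.hypot(10, 50)
        assert np.allclose(d, expect, atol=1e-12)

    def test_points_satisfy_two_point_line_equation(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            g = rng.uniform(-50, 50, 2) + [0, 100]
            n = rng.uniform(-50, 50, 2)
            if g[1] <= n[1]:
                continue
            ls = LandmarkSet.from_coords("s", {"G": tuple(g), "N": tuple(n)})
            nfl = construct_nfl(ls)
            for t in (-3.0, 0.0, 1.7, 10.0):
                p = nfl.point_at(t)
                # residual of the two-point line equation through G and N
                resid = (n[0] - g[0]) * (p[1] - g[1]) - (n[1] - g[1]) * (p[0] - g[0])
                assert abs(resid) < 1e-9 * max(1.0, np.linalg.norm(n - g))

    def test_degenerate_and_misordered(self):
        with pytest.raises(DegenerateGeometryError):
            construct_nfl(LandmarkSet.from_coords("s", {"G": (1, 1), "N": (1, 1)}))
        with pytest.raises(DegenerateGeometryError):
            construct_nfl(LandmarkSet.from_coords("s", {"G": (0, 0), "N": (0, 50)}))


class TestVerticalAnalysisLine:
    def test_closed_form_rotation_of_vertical_nfl(self):
        nfl = Line(anchor=np.array([0.0, 50.0]), direction=np.array([0.0, -1.0]))
        val = construct_val(nfl, np.array([0.0, 50.0]))
        s15, c15 = math.sin(math.radians(15)), math.cos(math.radians(15))
        assert np.allclose(val.direction, [-s15, -c15], atol=1e-12)
        assert np.allclose(val.anchor, [0, 50])

    def test_angle_to_nfl_is_always_fifteen_degrees(self):
        for ls in random_profiles(50, seed=21):
            nfl = construct_nfl(ls)
            val = construct_val(nfl, ls["N"])
            ang = abs(signed_angle_deg(nfl.direction, val.direction))
            assert ang == pytest.approx(15.0, abs=1e-9)

    def test_rotating_landmarks_rotates_val_identically(self, template):
        th = 30.0
        val0 = construct_val(construct_nfl(template), template["N"])
        rotated = template.transformed(rotation_deg=th)
        val1 = construct_val(construct_nfl(rotated), rotated["N"])
        r = math.radians(th)
        rot = np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])
        assert np.allclose(rot @ val0.direction, val1.direction, atol=1e-12)

    def test_anterior_sense_is_mirror(self):
        nfl = Line(anchor=np.zeros(2), direction=np.array([0.0, -1.0]))
        post = construct_val(nfl, np.zeros(2), rotation_sense="posterior")
        ant = construct_val(nfl, np.zeros(2), rotation_sense="anterior")
        assert post.direction[0] == pytest.approx(-ant.direction[0], abs=1e-12)


class TestHeights:
    def test_collinear_vertical_configuration(self):
        ls = LandmarkSet.from_coords(
            "s", {"N": (0, 100), "Sn": (0, 45), "St": (0, 23), "Me": (0, -21)}
        )
        val = Line(anchor=np.array([0.0, 100.0]), direction=np.array([0.0, -1.0]))
        assert measure_heights(ls, val) == pytest.approx((55, 22, 44), abs=1e-12)

    def test_coincident_landmarks_give_zero_height(self):
        ls = LandmarkSet.from_coords(
            "s", {"N": (0, 100), "Sn": (1, 45), "St": (1, 45), "Me": (0, -21)}
        )
        val = Line(anchor=np.zeros(2), direction=np.array([0.0, -1.0]))
        assert measure_heights(ls, val)[1] == 0.0

    def test_missing_landmark_named_in_error(self):
        ls = LandmarkSet.from_coords("s", {"N": (0, 100), "Sn": (0, 45), "St": (0, 23)})
        val = Line(anchor=np.zeros(2), direction=np.array([0.0, -1.0]))
        with pytest.raises(MissingLandmarkError, match="Me"):
            measure_heights(ls, val)


class TestInclinations:
    def test_parallel_structure_line_is_zero(self, template):
        val = construct_val(construct_nfl(template), template["N"])
        assert signed_angle_deg(val.direction, val.direction) == 0.0

    def test_right_triangle_closed_form_and_ventral_sign(self):
        # lip line 5 anterior over 15 caudal against a vertical VAL
        val = Line(anchor=np.zeros(2), direction=np.array([0.0, -1.0]))
        lip = np.array([5.0, -15.0])
        lip = lip / np.linalg.norm(lip)
        ang = signed_angle_deg(val.direction, lip)
        assert ang == pytest.approx(math.degrees(math.atan(5 / 15)), abs=1e-9)
        assert ang > 0  # anterior caudal end = ventral = positive

    def test_degenerate_structure_line(self, template):
        bad = dict(
            (n, (lm.x, lm.y)) for n, lm in template.landmarks.items()
        )
        bad["Prn"] = bad["N"]
        ls = LandmarkSet.from_coords("s", bad)
        val = construct_val(construct_nfl(ls), ls["N"])
        with pytest.raises(DegenerateGeometryError):
            measure_inclinations(ls, val)


class TestFullProfile:
    def test_matches_independent_oracle_on_random_sets(self):
        for ls in random_profiles(200, seed=5):
            coords = {n: (lm.x, lm.y) for n, lm in ls.landmarks.items()}
            expect = oracle_profile(coords, ls.scale)
            got = measure_profile(ls).as_dict()
            for k, v in expect.items():
                assert got[k] == pytest.approx(v, abs=1e-9), k

    def test_translation_invariance(self, template):
        m0 = measure_profile(template)
        m1 = measure_profile(template.transformed(translation=(37.0, -12.0)))
        for k, v in m0.as_dict().items():
            assert m1.as_dict()[k] == pytest.approx(v, abs=1e-9)

    def test_calibration_consistency_under_rescaling(self, template):
        m0 = measure_profile(template)
        doubled = template.transformed(scale_factor=2.0, new_scale=template.scale / 2.0)
        m1 = measure_profile(doubled)
        assert m1.heights == pytest.approx(m0.heights, abs=1e-9)
        assert m1.angles == pytest.approx(m0.angles, abs=1e-9)

    def test_similarity_invariance_of_angles(self):
        rng = np.random.default_rng(9)
        for ls in random_profiles(60, seed=13):
            m0 = measure_profile(ls)
            t = ls.transformed(
                rotation_deg=float(rng.uniform(-40, 40)),
                translation=tuple(rng.uniform(-100, 100, 2)),
                scale_factor=float(rng.uniform(0.3, 3.0)),
            )
            m1 = measure_profile(t)
            assert m1.angles == pytest.approx(m0.angles, abs=1e-9)
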