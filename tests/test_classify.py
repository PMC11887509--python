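"""Normative bands, harmony categories, boundaries, and advisory rules."""

import numpy as np
import pytest

from faceharmony.classify import (
    HarmonyClassification,
    classify_profile,
    classify_vertical,
    harmony_success,
    recommend_procedures,
)
from faceharmony.errors import InvalidMeasurementError
from faceharmony.geometry import ProfileMeasurements, measure_profile
from faceharmony.normative import (
    GOLDEN_RATIO,
    NormativeModel,
    SagittalRule,
    sagittal_band,
    vertical_band,
)

from conftest import random_profiles


class TestVerticalBand:
    def test_golden_section_of_upper_lip_height(self):
        opt, lo, hi = vertical_band(nasfh=50.0, maxfh=22.0)
        assert opt == pytest.approx(35.597, abs=1e-3)
        assert lo == pytest.approx(32.037, abs=1e-3)
        assert hi == pytest.approx(39.156, abs=1e-3)
        assert opt == pytest.approx(GOLDEN_RATIO * 22.0, abs=1e-12)

    def test_identity_rule_override(self):
        model = NormativeModel().with_vertical_rule(lambda nas, mx, phi: nas)
        opt, _, _ = vertical_band(41.5, 20.0, model)
        assert opt == 41.5

    def test_limits_strictly_bracket_optimum(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            nas, mx = rng.uniform(5, 80, 2)
            opt, lo, hi = vertical_band(nas, mx)
            assert lo < opt < hi

    def test_non_positive_heights_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            vertical_band(0.0, 22.0)
        with pytest.raises(InvalidMeasurementError):
            vertical_band(50.0, -1.0)


class TestClassifyVertical:
    @pytest.fixture
    def band(self):
        return vertical_band(50.0, 22.0)

    def test_optimum_is_normal(self, band):
        assert classify_vertical(band[0], band) == "NF"

    def test_boundaries_inclusive_toward_normal(self, band):
        assert classify_vertical(band[1], band) == "NF"
        assert classify_vertical(band[2], band) == "NF"

    def test_strict_exceedance_classified(self, band):
        assert classify_vertical(band[2] + 0.001, band) == "LF"
        assert classify_vertical(band[1] - 0.001, band) == "SF"


class TestSagittalBand:
    def test_zero_slope_independent_of_nri(self):
        model = NormativeModel(
            sagittal={p: SagittalRule(intercept=3.0, slope=0.0, halfwidth=4.0)
                      for p in ("OLI", "ULI", "MI")}
        )
        assert sagittal_band("OLI", 10.0, model) == sagittal_band("OLI", 55.0, model)
        assert sagittal_band("OLI", 0.0, model) == (-1.0, 7.0)

    def test_default_band_at_zero_nri(self):
        model = NormativeModel()
        r = model.sagittal["MI"]
        assert sagittal_band("MI", 0.0, model) == (r.intercept - r.halfwidth,
                                                   r.intercept + r.halfwidth)

    def test_width_is_twice_halfwidth(self):
        model = NormativeModel()
        for nri in (-10.0, 0.0, 33.3, 60.0):
            lo, hi = sagittal_band("ULI", nri, model)
            assert hi - lo == pytest.approx(2 * model.sagittal["ULI"].halfwidth)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            sagittal_band("NRI", 0.0)


def _centered_measurements(model: NormativeModel, nri: float = 40.0) -> ProfileMeasurements:
    maxfh = 22.0
    opt = model.mandfh_opt(50.0, maxfh)
    centres = {p: sum(model.sagittal[p].band(nri)) / 2 for p in ("OLI", "ULI", "MI")}
    return ProfileMeasurements(
        NasFH=50.0, MaxFH=maxfh, MandFH=opt,
        NRI=nri, OLI=centres["OLI"], ULI=centres["ULI"], MI=centres["MI"],
    )


class TestClassifyProfile:
    def test_band_centres_are_harmonious(self):
        model = NormativeModel()
        c = classify_profile(_centered_measurements(model), model)
        assert c.as_dict() == {
            "vertical": "NF", "OLI": "N", "ULI": "N", "MI": "N", "overall_harmony": True,
        }

    def test_single_violation_breaks_harmony(self):
        model = NormativeModel()
        m = _centered_measurements(model)
        low_mi = ProfileMeasurements(**{**m.as_dict(), "MI": model.sagittal["MI"].band(m.NRI)[0] - 1})
        c = classify_profile(low_mi, model)
        assert c.mi_category == "L"
        assert not c.overall_harmony
        assert c.vertical_category == "NF" and c.oli_category == "N"

    def test_matches_bruteforce_inequality_oracle(self):
        model = NormativeModel()
        rng = np.random.default_rng(17)
        for _ in range(1000):
            m = ProfileMeasurements(
                NasFH=rng.uniform(20, 60), MaxFH=rng.uniform(10, 35),
                MandFH=rng.uniform(10, 70), NRI=rng.uniform(0, 80),
                OLI=rng.uniform(-40, 80), ULI=rng.uniform(-40, 80), MI=rng.uniform(-40, 80),
            )
            c = classify_profile(m, model)
            # independent re-check: plain arithmetic on the model constants
            opt = model.phi * m.MaxFH
            lo, hi = 0.9 * opt, 1.1 * opt
            expect_v = "SF" if m.MandFH < lo else ("LF" if m.MandFH > hi else "NF")
            assert c.vertical_category == expect_v
            flags = [expect_v == "NF"]
            for p, cat in (("OLI", c.oli_category), ("ULI", c.uli_category), ("MI", c.mi_category)):
                r = model.sagittal[p]
                centre = r.intercept + r.slope * m.NRI
                v = getattr(m, p)
                expect = "L" if v < centre - r.halfwidth else (
                    "H" if v > centre + r.halfwidth else "N")
                assert cat == expect, p
                flags.append(expect == "N")
            assert c.overall_harmony == all(flags)

    def test_classification_similarity_invariant_from_landmarks(self):
        model = NormativeModel()
        rng = np.random.default_rng(8)
        for ls in random_profiles(40, seed=31):
            c0 = classify_profile(measure_profile(ls), model)
            t = ls.transformed(
                rotation_deg=float(rng.uniform(-30, 30)),
                translation=tuple(rng.uniform(-80, 80, 2)),
            )
            assert classify_profile(measure_profile(t), model).as_dict() == c0.as_dict()


class TestSuccessAndAdvisories:
    def test_success_is_post_state_alone(self):
        post_nf = HarmonyClassification("NF", "N", "N", "H")
        assert harmony_success(post_nf, "vertical")
        assert not harmony_success(post_nf, "MI")
        # a pre-operative LF is irrelevant by definition
        assert harmony_success(HarmonyClassification("NF", "N", "N", "N"), "vertical")

    def test_unknown_dimension_rejected(self):
        with pytest.raises(ValueError):
            harmony_success(HarmonyClassification("NF", "N", "N", "N"), "nose")

    def test_harmonious_profile_gets_no_advisories(self):
        c = HarmonyClassification("NF", "N", "N", "N")
        assert recommend_procedures(c, "II") == []

    def test_class_ii_low_chin_triggers_genioplasty_rule(self):
        c = HarmonyClassification("NF", "N", "N", "L")
        recs = recommend_procedures(c, "II")
        assert len(recs) == 1 and "genioplasty-advancement" in recs[0]
        assert recs[0].startswith("ADVISORY")
        assert recommend_procedures(c, "III") == []

    def test_class_iii_long_face_triggers_bimax_rule(self):
        c = HarmonyClassification("LF", "N", "N", "N")
        recs = recommend_procedures(c, "III")
        assert len(recs) == 1 and "bimax-rotation-setback" in recs[0]


class TestModelConfigRoundTrip:
    def test_dict_round_trip_lossless(self):
        model = NormativeModel(
            phi=1.6,
            band_fraction=0.12,
            sagittal={
                "OLI": SagittalRule(1.0, 0.4, 6.0),
                "ULI": SagittalRule(-2.0, 0.55, 5.5),
                "MI": SagittalRule(0.5, 0.45, 7.0),
            },
        )
        assert NormativeModel.from_dict(model.to_dict()) == model
        assert NormativeModel.from_dict(NormativeModel().to_dict()) == NormativeModel()
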