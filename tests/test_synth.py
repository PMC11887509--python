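"""Synthetic profiles and cohorts: determinism, targeting, calibration."""

import numpy as np
import pytest

from faceharmony.errors import InvalidDeformationError, InvalidMeasurementError
from faceharmony.geometry import measure_profile
from faceharmony.reference_cohort import HARMONY_BY_CLASS, PREVALENCE_COUNTS
from faceharmony.synth import (
    TEMPLATE_MEASUREMENTS,
    CohortSpec,
    Deformation,
    generate_cohort,
    generate_profile,
    profile_template,
    table_calibrated_spec,
)

from conftest import oracle_profile

DIMS = ("vertical", "OLI", "ULI", "MI")
KEYS = ("NasFH", "MaxFH", "MandFH", "NRI", "OLI", "ULI", "MI")


class TestTemplate:
    def test_documented_measurements_reproduced(self):
        m = measure_profile(profile_template())
        for k in KEYS:
            assert getattr(m, k) == pytest.approx(getattr(TEMPLATE_MEASUREMENTS, k), abs=1e-6)

    def test_documented_measurements_match_independent_oracle(self):
        t = profile_template()
        expect = oracle_profile({n: (lm.x, lm.y) for n, lm in t.landmarks.items()})
        for k in KEYS:
            assert getattr(TEMPLATE_MEASUREMENTS, k) == pytest.approx(expect[k], abs=1e-9)

    def test_template_is_harmonious(self):
        from faceharmony.classify import classify_profile

        assert classify_profile(measure_profile(profile_template())).overall_harmony


class TestProfileDeformations:
    def test_zero_deformation_is_identity(self):
        t = profile_template()
        out = generate_profile(t, Deformation(), noise_sd=0.0, seed=0)
        for n in t.landmarks:
            assert np.array_equal(out[n], t[n])

    @pytest.mark.parametrize(
        "deformation, changed",
        [
            (Deformation(mandible_shift_mm=-8.0), {"ULI", "MI"}),
            (Deformation(mandible_shift_mm=5.0), {"ULI", "MI"}),
            (Deformation(maxilla_shift_mm=4.0), {"OLI"}),
            (Deformation(elongation=0.2), {"MandFH"}),
            (Deformation(elongation=-0.15), {"MandFH"}),
        ],
    )
    def test_deformations_target_only_their_dimensions(self, deformation, changed):
        m0 = TEMPLATE_MEASUREMENTS
        m1 = measure_profile(generate_profile(deformation=deformation, noise_sd=0.0))
        for k in KEYS:
            delta = getattr(m1, k) - getattr(m0, k)
            if k in changed:
                assert abs(delta) > 1e-6, k
            else:
                assert abs(delta) < 1e-9, k

    def test_posterior_mandible_shift_decreases_chin_inclination(self):
        m1 = measure_profile(generate_profile(deformation=Deformation(mandible_shift_mm=-8.0)))
        assert m1.MI < TEMPLATE_MEASUREMENTS.MI
        assert m1.heights == pytest.approx(TEMPLATE_MEASUREMENTS.heights, abs=1e-9)

    def test_elongation_scales_lower_face_height(self):
        m1 = measure_profile(generate_profile(deformation=Deformation(elongation=0.2)))
        assert m1.MandFH == pytest.approx(1.2 * TEMPLATE_MEASUREMENTS.MandFH, abs=1e-9)

    def test_noise_determinism_contract(self):
        a = generate_profile(noise_sd=0.6, seed=123)
        b = generate_profile(noise_sd=0.6, seed=123)
        c = generate_profile(noise_sd=0.6, seed=124)
        assert all(np.array_equal(a[n], b[n]) for n in a.landmarks)
        assert any(not np.array_equal(a[n], c[n]) for n in a.landmarks)

    def test_ordering_violation_raises(self):
        with pytest.raises(InvalidDeformationError):
            generate_profile(deformation=Deformation(elongation=-1.05))

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            generate_profile(noise_sd=-0.1)


class TestCohortGeneration:
    def test_exact_count_margins(self):
        from collections import Counter

        cohort = generate_cohort(table_calibrated_spec(seed=4))
        assert Counter(r.angle_class for r in cohort) == {"I": 4, "II": 64, "III": 92}
        assert Counter(r.surgery for r in cohort) == {"LeFort1": 13, "BSSO": 24, "Bimax": 123}
        assert Counter(r.sex for r in cohort) == {"female": 99, "male": 61}

    def test_degenerate_pre_probability(self):
        spec = table_calibrated_spec(seed=0)
        spec = CohortSpec(**{**spec.__dict__, "pre_harmony": {d: 1.0 for d in DIMS}})
        cohort = generate_cohort(spec)
        assert all(r.pre.vertical_category == "NF" for r in cohort)
        assert all(r.pre.in_range(d) for r in cohort for d in DIMS)

    def test_bit_reproducible_per_seed(self):
        spec = table_calibrated_spec(seed=7)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert a == b
        assert generate_cohort(spec, seed=8) != a

    def test_infeasible_exact_counts_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            CohortSpec(n=100, class_counts={"I": 4, "II": 64, "III": 92})

    def test_age_model_respects_range(self):
        cohort = generate_cohort(table_calibrated_spec(seed=5))
        ages = [r.age for r in cohort]
        assert min(ages) >= 13.0 and max(ages) <= 61.0

    def test_probabilistic_margins_converge_at_large_n(self):
        # law-of-large-numbers check on the Bernoulli harmony draws
        n = 10_000
        spec = CohortSpec(
            n=n,
            class_counts={"I": 250, "II": 4000, "III": 5750},
            surgery_counts={"LeFort1": 800, "BSSO": 1500, "Bimax": 7700},
            sex_counts={"female": 6200, "male": 3800},
            pre_harmony={d: p for d, p in zip(DIMS, (0.42, 0.66, 0.59, 0.68))},
        )
        cohort = generate_cohort(spec, seed=12)
        for d, p in zip(DIMS, (0.42, 0.66, 0.59, 0.68)):
            frac = sum(r.pre.in_range(d) for r in cohort) / n
            se = (p * (1 - p) / n) ** 0.5
            assert abs(frac - p) < 4 * se, d


class TestTableCalibratedSpec:
    def test_expected_class_conditional_counts_match_reference(self):
        spec = table_calibrated_spec()
        for d, by_class in HARMONY_BY_CLASS.items():
            for cls, (yes, no) in by_class.items():
                expected = spec.post_success[d][cls] * (yes + no)
                assert expected == pytest.approx(yes, abs=1e-9)

    def test_expected_total_uli_successes(self):
        spec = table_calibrated_spec()
        total = sum(
            spec.post_success["ULI"][cls] * spec.class_counts[cls]
            for cls in ("I", "II", "III")
        )
        assert total == pytest.approx(138.0, abs=1e-9)

    def test_pre_probabilities_match_reference_rates(self):
        spec = table_calibrated_spec()
        for d, counts in PREVALENCE_COUNTS.items():
            yes, no = counts["pre"]
            assert spec.pre_harmony[d] == pytest.approx(yes / (yes + no), abs=1e-12)
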