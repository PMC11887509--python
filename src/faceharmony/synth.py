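"""Synthetic landmark profiles and cohorts.

Two generators make the whole pipeline testable without any external
data:

* :func:`generate_profile` deforms a canonical harmonious profile
  template with sagittal block shifts of the jaws (emulating Class II /
  Class III phenotypes), lower-face elongation (long-face phenotypes)
  and isotropic Gaussian landmark noise (tracing error).
* :func:`generate_cohort` draws patient records whose demographic
  margins, pre-operative harmony rates and class-conditional
  post-operative success rates follow a :class:`CohortSpec`;
  :func:`table_calibrated_spec` returns the spec calibrated to the
  bundled reference-cohort margins.

Every generator takes an explicit seed and is bit-reproducible; there is
no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import HarmonyClassification
from .cohort import PatientRecord
from .errors import InvalidDeformationError, InvalidMeasurementError
from .geometry import ProfileMeasurements
from .landmarks import Landmark, LandmarkSet
from .reference_cohort import (
    AGE_MEDIAN,
    AGE_RANGE,
    CLASS_COUNTS,
    HARMONY_BY_CLASS,
    PREVALENCE_COUNTS,
    SEX_COUNTS,
    SURGERY_COUNTS,
)

#: Canonical harmonious profile in mm (x anterior-positive, y
#: superior-positive, subject facing +x).  Proportions follow the
#: golden-section vertical norm and centred sagittal bands.
TEMPLATE_COORDS: dict[str, tuple[float, float]] = {
    "G": (0.0, 112.0),
    "N": (0.0, 100.0),
    "Prn": (20.0, 74.0),
    "Sn": (12.0, 66.0),
    "Ls": (14.8, 52.0),
    "St": (12.0, 44.0),
    "Li": (13.7, 36.0),
    "Pg": (17.5, 14.0),
    "Me": (6.0, 9.0),
}

#: Measurements of the template, frozen from the geometry pipeline and
#: independently verified against a dot-product/atan2 oracle in the test
#: suite; measure_profile(profile_template()) must reproduce these to 1e-6.
TEMPLATE_MEASUREMENTS = ProfileMeasurements(
    NasFH=29.735649552598073,
    MaxFH=21.2503681783595,
    MandFH=35.360318190732514,
    NRI=52.568592028827496,
    OLI=26.309932474020215,
    ULI=26.99689930792357,
    MI=25.388857815469613,
)

#: Landmarks translated by a mandibular sagittal shift.  Stomion stays
#: with the upper face: it is the contact point of both lips, and the
#: chin and lower-lip structure lines (St-Pg, St-Li) are anchored there —
#: a block containing both endpoints of a line could never change its
#: inclination.
MANDIBLE_BLOCK = ("Li", "Pg", "Me")
#: Upper-lip landmark moved fully by a maxillary shift; subnasale
#: follows at this soft-tissue response ratio.
MAXILLA_SN_RATIO = 0.5


def profile_template(subject_id: str = "template") -> LandmarkSet:
    """A fresh copy of the canonical harmonious landmark template."""
    return LandmarkSet.from_coords(subject_id, TEMPLATE_COORDS)


@dataclass(frozen=True)
class Deformation:
    """Sagittal/vertical deformation of a profile template.

    Shifts are applied perpendicular to the template's vertical analysis
    line (the sagittal direction of the analysis), so the three facial
    heights — projections onto the VAL — are exactly invariant under
    them, and each deformation perturbs only the measurements it
    targets.

    mandible_shift_mm:
        Anterior (+) / posterior (-) shift of Li, Pg, Me — a crude
        mandibular advancement/setback (a retrusive Class II chin is a
        negative shift, a protrusive Class III chin positive).  Targets
        ULI and MI.
    maxilla_shift_mm:
        Shift of the upper lip (Ls), with subnasale following at half
        the displacement (soft-tissue response).  Targets OLI.
    elongation:
        Fractional vertical scaling of the lower face: Li, Pg, Me are
        scaled radially about stomion by (1 + elongation), which changes
        MandFH (+0.15 = a 15 % longer lower face) while preserving the
        St-anchored structure-line directions, hence ULI and MI.
    """

    mandible_shift_mm: float = 0.0
    maxilla_shift_mm: float = 0.0
    elongation: float = 0.0


def generate_profile(
    template: LandmarkSet | None = None,
    deformation: Deformation | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> LandmarkSet:
    """Deform the template and add landmark noise; deterministic per seed.

    Block shifts move the mandibular (St, Li, Pg, Me) and maxillary
    (Sn, Ls) landmarks sagittally as rigid units; elongation rescales
    the vertical St-Me span about stomion.  Isotropic Gaussian noise of
    ``noise_sd`` mm is then added to every landmark.  Raises
    :class:`InvalidDeformationError` if the result violates the
    superior-to-inferior ordering invariant.
    """
    from .geometry import construct_nfl, construct_val

    template = template or profile_template()
    d = deformation or Deformation()
    if noise_sd < 0:
        raise InvalidMeasurementError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    # sagittal unit vector: perpendicular to the template's VAL, anterior
    val = construct_val(construct_nfl(template), template["N"])
    sag = np.array([-val.direction[1], val.direction[0]])
    if sag[0] < 0:
        sag = -sag
    st = template["St"]
    out: dict[str, Landmark] = {}
    for name, lm in template.landmarks.items():
        p = lm.xy
        if d.elongation != 0.0 and name in MANDIBLE_BLOCK:
            p = st + (1.0 + d.elongation) * (p - st)
        if name in MANDIBLE_BLOCK:
            p = p + d.mandible_shift_mm * sag
        if name == "Ls":
            p = p + d.maxilla_shift_mm * sag
        elif name == "Sn":
            p = p + MAXILLA_SN_RATIO * d.maxilla_shift_mm * sag
        out[name] = Landmark(name, float(p[0]), float(p[1]), lm.unit)
    if noise_sd > 0:
        for name, lm in out.items():
            dx, dy = rng.normal(0.0, noise_sd, size=2)
            out[name] = Landmark(name, lm.x + dx, lm.y + dy, lm.unit)
    result = LandmarkSet(
        subject_id=template.subject_id, landmarks=out, scale=template.scale
    )
    try:
        result.validate_full()
    except Exception as e:
        raise InvalidDeformationError(
            f"deformation {d} with noise_sd={noise_sd} broke landmark ordering: {e}"
        ) from e
    return result


# ---- cohorts ---------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for a synthetic patient cohort.

    Mixes given as exact integer counts (summing to ``n``) are hit
    exactly; the harmony states are Bernoulli draws: pre-operative
    harmony with probability ``pre_harmony[dim]``, post-operative
    success with probability ``post_success[dim][angle_class]``
    (optionally modulated additively by ``post_pre_bonus`` when the same
    dimension was already harmonious pre-operatively).  Ages are
    lognormal with the given median, truncated to ``age_range``.
    """

    n: int = 160
    class_counts: dict[str, int] = field(default_factory=lambda: dict(CLASS_COUNTS))
    surgery_counts: dict[str, int] = field(default_factory=lambda: dict(SURGERY_COUNTS))
    sex_counts: dict[str, int] = field(default_factory=lambda: dict(SEX_COUNTS))
    age_median: float = AGE_MEDIAN
    age_sigma: float = 0.35
    age_range: tuple[float, float] = AGE_RANGE
    pre_harmony: dict[str, float] = field(
        default_factory=lambda: {d: 0.6 for d in ("vertical", "OLI", "ULI", "MI")}
    )
    post_success: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            d: {c: 0.7 for c in ("I", "II", "III")}
            for d in ("vertical", "OLI", "ULI", "MI")
        }
    )
    post_pre_bonus: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mix_name in ("class_counts", "surgery_counts", "sex_counts"):
            mix = getattr(self, mix_name)
            if sum(mix.values()) != self.n:
                raise InvalidMeasurementError(
                    f"{mix_name} must sum to n={self.n}, got {sum(mix.values())}"
                )
            if any(v < 0 for v in mix.values()):
                raise InvalidMeasurementError(f"{mix_name} has negative counts")
        for d, p in self.pre_harmony.items():
            if not 0 <= p <= 1:
                raise InvalidMeasurementError(f"pre_harmony[{d}]={p} outside [0, 1]")
        for d, by_class in self.post_success.items():
            for c, p in by_class.items():
                lo = min(p, p + self.post_pre_bonus)
                hi = max(p, p + self.post_pre_bonus)
                if not (0 <= lo and hi <= 1):
                    raise InvalidMeasurementError(
                        f"post_success[{d}][{c}]={p} with bonus "
                        f"{self.post_pre_bonus} leaves [0, 1]"
                    )


_DIM_CODES = {
    "vertical": ("NF", "SF", "LF"),
    "OLI": ("N", "L", "H"),
    "ULI": ("N", "L", "H"),
    "MI": ("N", "L", "H"),
}


def _draw_category(dim: str, harmonious: bool, rng: np.random.Generator) -> str:
    normal, low, high = _DIM_CODES[dim]
    if harmonious:
        return normal
    return low if rng.random() < 0.5 else high


def _exact_assignment(mix: dict[str, int], rng: np.random.Generator) -> list[str]:
    pool = [k for k, v in mix.items() for _ in range(v)]
    return [pool[i] for i in rng.permutation(len(pool))]


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[PatientRecord]:
    """Sample a cohort per the spec; the seed overrides ``spec.seed``."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    classes = _exact_assignment(spec.class_counts, rng)
    surgeries = _exact_assignment(spec.surgery_counts, rng)
    sexes = _exact_assignment(spec.sex_counts, rng)
    lo, hi = spec.age_range
    mu = math.log(spec.age_median)
    records: list[PatientRecord] = []
    for i in range(spec.n):
        age = float(np.clip(rng.lognormal(mu, spec.age_sigma), lo, hi))
        pre_cat = {}
        post_cat = {}
        for dim in ("vertical", "OLI", "ULI", "MI"):
            pre_ok = rng.random() < spec.pre_harmony[dim]
            p_post = spec.post_success[dim][classes[i]]
            if pre_ok:
                p_post = p_post + spec.post_pre_bonus
            post_ok = rng.random() < p_post
            pre_cat[dim] = _draw_category(dim, pre_ok, rng)
            post_cat[dim] = _draw_category(dim, post_ok, rng)
        records.append(
            PatientRecord(
                id=f"S{i + 1:04d}",
                sex=sexes[i],
                age=age,
                angle_class=classes[i],
                surgery=surgeries[i],
                pre=HarmonyClassification(
                    vertical_category=pre_cat["vertical"],
                    oli_category=pre_cat["OLI"],
                    uli_category=pre_cat["ULI"],
                    mi_category=pre_cat["MI"],
                ),
                post=HarmonyClassification(
                    vertical_category=post_cat["vertical"],
                    oli_category=post_cat["OLI"],
                    uli_category=post_cat["ULI"],
                    mi_category=post_cat["MI"],
                ),
            )
        )
    return records


def table_calibrated_spec(seed: int = 0) -> CohortSpec:
    """The cohort spec calibrated to the bundled reference margins.

    Pre-operative harmony probabilities are the overall pre rates;
    post-operative success probabilities are the per-Angle-class
    harmonious fractions, so the expected per-class success counts equal
    the reference by-class counts exactly.
    """
    pre = {
        d: counts["pre"][0] / sum(counts["pre"])
        for d, counts in PREVALENCE_COUNTS.items()
    }
    post = {
        d: {c: yes / (yes + no) for c, (yes, no) in by_class.items()}
        for d, by_class in HARMONY_BY_CLASS.items()
    }
    return CohortSpec(pre_harmony=pre, post_success=post, seed=seed)
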