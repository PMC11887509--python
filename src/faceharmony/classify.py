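"""Harmony classification of a measured profile, and advisory rules.

Each profile is judged in four dimensions: the vertical dimension
(mandibulofacial height against its golden-section band) and the three
sagittal inclinations (against their NRI-dependent bands).  A value
exactly on a band limit counts as in range; clinically, ties are
reported as within normal limits.  Facial harmony holds when all four
dimensions are in their normal range.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import ProfileMeasurements
from .normative import NormativeModel, sagittal_band, vertical_band

VERTICAL_CATEGORIES = ("SF", "NF", "LF")  # short face / normal / long face
SAGITTAL_CATEGORIES = ("L", "N", "H")  # too low / normal / too high
DIMENSIONS = ("vertical", "OLI", "ULI", "MI")


@dataclass(frozen=True)
class HarmonyClassification:
    """Per-dimension categories plus the overall harmony flag."""

    vertical_category: str
    oli_category: str
    uli_category: str
    mi_category: str

    def __post_init__(self) -> None:
        if self.vertical_category not in VERTICAL_CATEGORIES:
            raise ValueError(f"bad vertical category {self.vertical_category!r}")
        for a in ("oli_category", "uli_category", "mi_category"):
            if getattr(self, a) not in SAGITTAL_CATEGORIES:
                raise ValueError(f"bad {a} {getattr(self, a)!r}")

    def category(self, dimension: str) -> str:
        return {
            "vertical": self.vertical_category,
            "OLI": self.oli_category,
            "ULI": self.uli_category,
            "MI": self.mi_category,
        }[dimension]

    def in_range(self, dimension: str) -> bool:
        return self.category(dimension) in ("NF", "N")

    @property
    def overall_harmony(self) -> bool:
        return all(self.in_range(d) for d in DIMENSIONS)

    def as_dict(self) -> dict:
        return {
            "vertical": self.vertical_category,
            "OLI": self.oli_category,
            "ULI": self.uli_category,
            "MI": self.mi_category,
            "overall_harmony": self.overall_harmony,
        }


def classify_vertical(mandfh: float, band: tuple[float, float, float]) -> str:
    """SF / NF / LF for a measured MandFH against (opt, SF_limit, LF_limit)."""
    _, lo, hi = band
    if mandfh < lo:
        return "SF"
    if mandfh > hi:
        return "LF"
    return "NF"


def _classify_sagittal(value: float, band: tuple[float, float]) -> str:
    lo, hi = band
    if value < lo:
        return "L"
    if value > hi:
        return "H"
    return "N"


def classify_profile(
    m: ProfileMeasurements, model: NormativeModel | None = None
) -> HarmonyClassification:
    """Classify all four dimensions of a measured profile.

    For the chin, L (below band) corresponds to the dorsal/retrogenic
    label and H (above band) to the ventral/progenic label.
    """
    model = model or NormativeModel()
    vband = vertical_band(m.NasFH, m.MaxFH, model)
    return HarmonyClassification(
        vertical_category=classify_vertical(m.MandFH, vband),
        oli_category=_classify_sagittal(m.OLI, sagittal_band("OLI", m.NRI, model)),
        uli_category=_classify_sagittal(m.ULI, sagittal_band("ULI", m.NRI, model)),
        mi_category=_classify_sagittal(m.MI, sagittal_band("MI", m.NRI, model)),
    )


def harmony_success(post: HarmonyClassification, dimension: str) -> bool:
    """Success of one dimension: the post-operative category is in range.

    Success is defined on the post-operative state alone — a dimension
    kept within or transferred into the normal range counts equally.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    return post.in_range(dimension)


ADVISORY_PREFIX = "ADVISORY (non-normative, not a clinical directive): "

#: (rule id, predicate description, advisory text). Rules encode common
#: surgical heuristics for residual disharmony by Angle class.
_RULES = [
    (
        "genioplasty-advancement",
        lambda c, ac: ac == "II" and c.mi_category == "L",
        "Class II with low (dorsal) mandibular inclination: consider chin "
        "advancement / augmentation genioplasty, or a bimaxillary advancement "
        "if chin retrusion is severe.",
    ),
    (
        "bimax-rotation-setback",
        lambda c, ac: ac == "III" and c.vertical_category == "LF",
        "Class III with long-face configuration: consider a bimaxillary "
        "procedure rotating the bimaxillary block with a moderate mandibular "
        "setback, and/or a reduction genioplasty.",
    ),
]


def recommend_procedures(c: HarmonyClassification, angle_class: str) -> list[str]:
    """Advisory strings for residual disharmony; empty when harmonious.

    Output is deterministic rule lookup, prefixed to make its
    non-normative nature explicit; each string starts with its rule id.
    """
    if c.overall_harmony:
        return []
    out = []
    for rule_id, pred, text in _RULES:
        if pred(c, angle_class):
            out.append(f"{ADVISORY_PREFIX}[{rule_id}] {text}")
    return out
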