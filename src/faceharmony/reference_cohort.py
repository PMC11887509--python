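"""Bundled reference cohort margins (n = 160 orthognathic-surgery patients).

These are published summary counts from a retrospective cohort of 160
patients treated with orthognathic surgery: the prevalence of facial
harmony in each analysed dimension before and after surgery, the
post-operative harmony counts split by Angle class, and the cohort's
demographic and surgical margins.  Individual-level data were never
published; only these margins are bundled, and
:func:`margin_matched_cohort` builds a deterministic patient table that
reproduces every one of them exactly (the joint structure beyond the
margins is synthetic by construction).
"""

from __future__ import annotations

from .classify import HarmonyClassification
from .cohort import PatientRecord
from .exact import ContingencyTable
import numpy as np

#: Pre/post (harmonious, non-harmonious) counts per dimension, n=160.
PREVALENCE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "vertical": {"pre": (67, 93), "post": (99, 61)},
    "OLI": {"pre": (106, 54), "post": (95, 65)},
    "ULI": {"pre": (95, 65), "post": (138, 22)},
    "MI": {"pre": (109, 51), "post": (118, 42)},
}

#: Post-operative (harmonious, non-harmonious) counts by Angle class.
HARMONY_BY_CLASS: dict[str, dict[str, tuple[int, int]]] = {
    "vertical": {"I": (3, 1), "II": (47, 17), "III": (49, 43)},
    "OLI": {"I": (3, 1), "II": (40, 24), "III": (52, 40)},
    "ULI": {"I": (4, 0), "II": (57, 7), "III": (77, 15)},
    "MI": {"I": (4, 0), "II": (34, 30), "III": (80, 12)},
}

CLASS_COUNTS: dict[str, int] = {"I": 4, "II": 64, "III": 92}
SURGERY_COUNTS: dict[str, int] = {"LeFort1": 13, "BSSO": 24, "Bimax": 123}
SEX_COUNTS: dict[str, int] = {"female": 99, "male": 61}
AGE_RANGE: tuple[float, float] = (13.0, 61.0)
AGE_MEDIAN: float = 23.0
N_PATIENTS: int = 160

_DIM_CODES = {
    "vertical": ("NF", "SF", "LF"),
    "OLI": ("N", "L", "H"),
    "ULI": ("N", "L", "H"),
    "MI": ("N", "L", "H"),
}


def by_class_contingency(dimension: str) -> ContingencyTable:
    """The 3x2 Angle-class x harmony table for one dimension."""
    rows = HARMONY_BY_CLASS[dimension]
    counts = np.array([[rows[c][0], rows[c][1]] for c in ("I", "II", "III")])
    return ContingencyTable(
        counts,
        row_labels=("Class I", "Class II", "Class III"),
        col_labels=("Yes", "No"),
    )


def _category(dimension: str, harmonious: bool, alt_toggle: int) -> str:
    normal, low, high = _DIM_CODES[dimension]
    if harmonious:
        return normal
    return low if alt_toggle % 2 == 0 else high


def margin_matched_cohort() -> list[PatientRecord]:
    """A deterministic 160-patient table matching every bundled margin.

    Patients are laid out in Angle-class blocks (4 Class I, 64 Class II,
    92 Class III).  Within each class the first k patients of a
    dimension are post-operatively harmonious, where k is that class's
    harmonious count, so the by-class tables are exact; pre-operative
    harmony is assigned so the overall pre counts are exact.  Sex,
    surgery and age follow fixed cyclic assignments that reproduce the
    demographic margins; non-harmonious states alternate between the
    low and high code.  The joint distribution across dimensions is a
    modelling convention, not data.
    """
    classes: list[str] = (
        ["I"] * CLASS_COUNTS["I"] + ["II"] * CLASS_COUNTS["II"] + ["III"] * CLASS_COUNTS["III"]
    )
    n = len(classes)
    assert n == N_PATIENTS

    # post: per-class prefix assignment
    post_flags: dict[str, list[bool]] = {}
    for dim, rows in HARMONY_BY_CLASS.items():
        flags: list[bool] = []
        for cls in ("I", "II", "III"):
            yes, no = rows[cls]
            flags += [True] * yes + [False] * no
        post_flags[dim] = flags

    # pre: overall prefix assignment (per-class pre splits were not published)
    pre_flags: dict[str, list[bool]] = {}
    for dim, phases in PREVALENCE_COUNTS.items():
        yes, no = phases["pre"]
        pre_flags[dim] = [True] * yes + [False] * no

    sexes = ["female"] * SEX_COUNTS["female"] + ["male"] * SEX_COUNTS["male"]
    surgeries = (
        ["LeFort1"] * SURGERY_COUNTS["LeFort1"]
        + ["BSSO"] * SURGERY_COUNTS["BSSO"]
        + ["Bimax"] * SURGERY_COUNTS["Bimax"]
    )
    # interleave demographics against the class blocks so no margin is
    # confounded with class by construction alone
    order = [(i * 37) % n for i in range(n)]  # 37 coprime with 160
    # right-skewed age cycle spanning 13-61 with cohort median exactly 23
    age_cycle = (13, 16, 19, 21, 22, 24, 26, 29, 37, 61)

    records: list[PatientRecord] = []
    for i in range(n):
        j = order[i]
        age = age_cycle[i % len(age_cycle)]
        pre = HarmonyClassification(
            vertical_category=_category("vertical", pre_flags["vertical"][i], i),
            oli_category=_category("OLI", pre_flags["OLI"][i], i),
            uli_category=_category("ULI", pre_flags["ULI"][i], i),
            mi_category=_category("MI", pre_flags["MI"][i], i),
        )
        post = HarmonyClassification(
            vertical_category=_category("vertical", post_flags["vertical"][i], i + 1),
            oli_category=_category("OLI", post_flags["OLI"][i], i + 1),
            uli_category=_category("ULI", post_flags["ULI"][i], i + 1),
            mi_category=_category("MI", post_flags["MI"][i], i + 1),
        )
        records.append(
            PatientRecord(
                id=f"P{i + 1:03d}",
                sex=sexes[j],
                age=float(max(age, 13.0)),
                angle_class=classes[i],
                surgery=surgeries[j],
                pre=pre,
                post=post,
            )
        )
    return records
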