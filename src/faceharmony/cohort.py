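"""Patient records, cohort CSV schema, and outcome summary tables.

A cohort row carries demographics, Angle class, surgery type and the
pre- and post-operative harmony categories in each of the four analysed
dimensions (vertical as SF/NF/LF; OLI, ULI, MI as L/N/H).  Success in a
dimension means the post-operative category is in the normal range.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import DIMENSIONS, HarmonyClassification
from .errors import CohortSchemaError, InvalidMeasurementError
from .exact import ContingencyTable

SEXES = ("female", "male")
ANGLE_CLASSES = ("I", "II", "III")
SURGERIES = ("LeFort1", "BSSO", "Bimax")

CSV_COLUMNS = (
    "id", "sex", "age", "angle_class", "surgery",
    "pre_vertical", "pre_oli", "pre_uli", "pre_mi",
    "post_vertical", "post_oli", "post_uli", "post_mi",
)

_DIM_TO_COL = {"vertical": "vertical", "OLI": "oli", "ULI": "uli", "MI": "mi"}
_VERT_CODES = ("SF", "NF", "LF")
_SAG_CODES = ("L", "N", "H")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, surgery and pre/post harmony states."""

    id: str
    sex: str
    age: float
    angle_class: str
    surgery: str
    pre: HarmonyClassification
    post: HarmonyClassification

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidMeasurementError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age > 0:
            raise InvalidMeasurementError(f"age must be positive, got {self.age}")
        if self.angle_class not in ANGLE_CLASSES:
            raise InvalidMeasurementError(
                f"angle_class must be one of {ANGLE_CLASSES}, got {self.angle_class!r}"
            )
        if self.surgery not in SURGERIES:
            raise InvalidMeasurementError(
                f"surgery must be one of {SURGERIES}, got {self.surgery!r}"
            )

    def success(self, dimension: str) -> bool:
        return self.post.in_range(dimension)


# ---- CSV schema ------------------------------------------------------------


def _parse_classification(row: dict, phase: str, line: int, path: str) -> HarmonyClassification:
    vals = {}
    for dim, col in _DIM_TO_COL.items():
        key = f"{phase}_{col}"
        v = row[key].strip()
        allowed = _VERT_CODES if dim == "vertical" else _SAG_CODES
        if v not in allowed:
            raise CohortSchemaError(
                f"column {key!r}: invalid category {v!r} (allowed: {'/'.join(allowed)})",
                line=line, path=path,
            )
        vals[dim] = v
    return HarmonyClassification(
        vertical_category=vals["vertical"],
        oli_category=vals["OLI"],
        uli_category=vals["ULI"],
        mi_category=vals["MI"],
    )


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read and strictly validate a cohort CSV; errors carry line numbers."""
    path = Path(path)
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CSV_COLUMNS:
            raise CohortSchemaError(
                f"header must be exactly {','.join(CSV_COLUMNS)}", line=1, path=str(path)
            )
        for line, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in CSV_COLUMNS):
                raise CohortSchemaError("short record", line=line, path=str(path))
            try:
                age = float(row["age"])
            except ValueError:
                raise CohortSchemaError(
                    f"column 'age': not a number: {row['age']!r}", line=line, path=str(path)
                ) from None
            try:
                rec = PatientRecord(
                    id=row["id"].strip(),
                    sex=row["sex"].strip(),
                    age=age,
                    angle_class=row["angle_class"].strip(),
                    surgery=row["surgery"].strip(),
                    pre=_parse_classification(row, "pre", line, str(path)),
                    post=_parse_classification(row, "post", line, str(path)),
                )
            except InvalidMeasurementError as e:
                raise CohortSchemaError(str(e), line=line, path=str(path)) from None
            records.append(rec)
    if not records:
        raise CohortSchemaError("cohort is empty", path=str(path))
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            w.writerow([
                r.id, r.sex, f"{r.age:g}", r.angle_class, r.surgery,
                r.pre.vertical_category, r.pre.oli_category,
                r.pre.uli_category, r.pre.mi_category,
                r.post.vertical_category, r.post.oli_category,
                r.post.uli_category, r.post.mi_category,
            ])


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flat DataFrame view with per-dimension success indicator columns."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "sex": r.sex, "age": r.age,
            "angle_class": r.angle_class, "surgery": r.surgery,
            "pre_vertical": r.pre.vertical_category,
            "pre_oli": r.pre.oli_category,
            "pre_uli": r.pre.uli_category,
            "pre_mi": r.pre.mi_category,
            "post_vertical": r.post.vertical_category,
            "post_oli": r.post.oli_category,
            "post_uli": r.post.uli_category,
            "post_mi": r.post.mi_category,
        }
        for d in DIMENSIONS:
            row[f"success_{_DIM_TO_COL[d]}"] = int(r.success(d))
        rows.append(row)
    return pd.DataFrame(rows)


# ---- summary statistics ----------------------------------------------------


def prevalence_summary(
    records: Sequence[PatientRecord], dimension: str, phase: str, digits: int = 0
) -> tuple[int, int, float]:
    """(harmonious count, non-harmonious count, rounded percent harmonious).

    ``digits=0`` reports whole percent (overall prevalence tables);
    ``digits=1`` one decimal (per-class margins).
    """
    if not records:
        raise InvalidMeasurementError("empty cohort")
    if phase not in ("pre", "post"):
        raise InvalidMeasurementError(f"phase must be 'pre' or 'post', got {phase!r}")
    yes = sum(
        1 for r in records
        if (r.pre if phase == "pre" else r.post).in_range(dimension)
    )
    no = len(records) - yes
    pct = round(100.0 * yes / (yes + no), digits)
    return yes, no, float(pct) if digits else int(pct)


def improvement_delta(pre: tuple[int, int], post: tuple[int, int]) -> int:
    """Change in rounded percent harmonious, in percentage points.

    Both arguments are (harmonious, total).  Rounding happens before the
    subtraction, matching how summary percentages are reported; a
    negative value is a deterioration.
    """
    pre_yes, pre_total = pre
    post_yes, post_total = post
    if pre_total != post_total or pre_total <= 0:
        raise InvalidMeasurementError(
            f"pre/post totals must match and be positive, got {pre_total} and {post_total}"
        )
    return int(round(100.0 * post_yes / post_total) - round(100.0 * pre_yes / pre_total))


def harmony_by_class_table(
    records: Sequence[PatientRecord], dimension: str, phase: str = "post"
) -> ContingencyTable:
    """Angle class x (harmonious yes/no) contingency table for one dimension."""
    counts = np.zeros((3, 2), dtype=np.int64)
    for r in records:
        i = ANGLE_CLASSES.index(r.angle_class)
        ok = (r.pre if phase == "pre" else r.post).in_range(dimension)
        counts[i, 0 if ok else 1] += 1
    return ContingencyTable(
        counts,
        row_labels=tuple(f"Class {c}" for c in ANGLE_CLASSES),
        col_labels=("Yes", "No"),
    )


def prevalence_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Pre/post prevalence of harmony per dimension (overall cohort)."""
    rows = []
    for d in DIMENSIONS:
        pre_y, pre_n, pre_p = prevalence_summary(records, d, "pre")
        post_y, post_n, post_p = prevalence_summary(records, d, "post")
        rows.append({
            "dimension": d,
            "pre_yes": pre_y, "pre_no": pre_n, "pre_pct": pre_p,
            "post_yes": post_y, "post_no": post_n, "post_pct": post_p,
            "delta_pct_points": improvement_delta(
                (pre_y, pre_y + pre_n), (post_y, post_y + post_n)
            ),
        })
    return pd.DataFrame(rows)


def render_prevalence_text(table: pd.DataFrame) -> str:
    lines = ["Prevalence of facial harmony before and after surgery",
             f"{'Dimension':<10}{'Pre Yes':>8}{'Pre No':>8}{'Pre %':>7}"
             f"{'Post Yes':>10}{'Post No':>9}{'Post %':>8}{'Delta':>7}"]
    for _, r in table.iterrows():
        lines.append(
            f"{r['dimension']:<10}{r['pre_yes']:>8}{r['pre_no']:>8}{r['pre_pct']:>6}%"
            f"{r['post_yes']:>10}{r['post_no']:>9}{r['post_pct']:>7}%"
            f"{r['delta_pct_points']:>+7}"
        )
    return "\n".join(lines)
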