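"""Landmark file formats, the analysis report, and the pipeline driver.

Landmark sets are read and written in three interchangeable dialects:

* TPS — the geometric-morphometrics exchange format: an ``LM=`` count,
  one ``x y`` pair per line (in the fixed vocabulary order G, N, Prn,
  Sn, Ls, St, Li, Pg, Me, since TPS carries no point names), and
  optional ``ID=`` and ``SCALE=`` records; SCALE is honoured as
  mm-per-unit.
* CSV — a ``name,x,y`` table with a header row.
* JSON — a direct mirror of the LandmarkSet structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classify import HarmonyClassification, classify_profile, recommend_procedures
from .cohort import (
    PatientRecord,
    harmony_by_class_table,
    prevalence_table,
    read_cohort_csv,
)
from .config import PipelineConfig
from .errors import FaceHarmonyError, MissingLandmarkError, PipelineError
from .exact import fisher_freeman_halton, format_p
from .geometry import ProfileMeasurements, measure_profile
from .landmarks import VOCABULARY, Landmark, LandmarkSet

# ---- landmark readers/writers ---------------------------------------------


def write_tps(ls: LandmarkSet, path: str | Path) -> None:
    lines = [f"LM={len(VOCABULARY)}"]
    for name in VOCABULARY:
        p = ls[name]
        lines.append(f"{p[0]:.10g} {p[1]:.10g}")
    lines.append(f"ID={ls.subject_id}")
    lines.append(f"SCALE={ls.scale:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path: str | Path) -> list[LandmarkSet]:
    """Read one or more landmark sets from a TPS file.

    Points are assigned names in the fixed vocabulary order; a record
    with a different point count is rejected.
    """
    path = Path(path)
    sets: list[LandmarkSet] = []
    current: list[tuple[float, float]] | None = None
    subject = None
    scale = 1.0
    expect = 0

    def flush(line_no: int) -> None:
        nonlocal current, subject, scale
        if current is None:
            return
        if len(current) != expect:
            raise FaceHarmonyError(
                f"{path}:{line_no}: TPS record declares LM={expect} "
                f"but has {len(current)} points"
            )
        if expect != len(VOCABULARY):
            raise FaceHarmonyError(
                f"{path}:{line_no}: expected LM={len(VOCABULARY)} named profile "
                f"points, got LM={expect}"
            )
        coords = dict(zip(VOCABULARY, current))
        sets.append(
            LandmarkSet.from_coords(
                subject or f"tps{len(sets) + 1}", coords, scale=scale, unit="pixel" if scale != 1.0 else "mm"
            )
        )
        current, subject, scale = None, None, 1.0

    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush(line_no)
            expect = int(line.split("=", 1)[1])
            current = []
        elif upper.startswith("ID="):
            subject = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            scale = float(line.split("=", 1)[1])
        elif upper.startswith(("IMAGE=", "CURVES=", "POINTS=")):
            continue
        else:
            if current is None:
                raise FaceHarmonyError(f"{path}:{line_no}: point data before LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise FaceHarmonyError(f"{path}:{line_no}: malformed point line {raw!r}")
            current.append((float(parts[0]), float(parts[1])))
    flush(line_no if "line_no" in dir() else 0)
    if not sets:
        raise FaceHarmonyError(f"{path}: no TPS records found")
    return sets


def write_landmarks_csv(ls: LandmarkSet, path: str | Path) -> None:
    lines = ["name,x,y"]
    for name in VOCABULARY:
        if name in ls:
            p = ls[name]
            lines.append(f"{name},{p[0]:.10g},{p[1]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks_csv(path: str | Path, subject_id: str | None = None, scale: float = 1.0) -> LandmarkSet:
    path = Path(path)
    rows = path.read_text().splitlines()
    if not rows or [c.strip().lower() for c in rows[0].split(",")] != ["name", "x", "y"]:
        raise FaceHarmonyError(f"{path}:1: expected header 'name,x,y'")
    coords: dict[str, tuple[float, float]] = {}
    for line_no, raw in enumerate(rows[1:], start=2):
        if not raw.strip():
            continue
        parts = [p.strip() for p in raw.split(",")]
        if len(parts) != 3:
            raise FaceHarmonyError(f"{path}:{line_no}: malformed record {raw!r}")
        try:
            coords[parts[0]] = (float(parts[1]), float(parts[2]))
        except ValueError:
            raise FaceHarmonyError(
                f"{path}:{line_no}: non-numeric coordinate in {raw!r}"
            ) from None
    ls = LandmarkSet.from_coords(subject_id or path.stem, coords, scale=scale)
    return ls


def landmarks_to_json(ls: LandmarkSet) -> dict:
    return {
        "subject_id": ls.subject_id,
        "scale": ls.scale,
        "landmarks": {
            n: {"x": lm.x, "y": lm.y, "unit": lm.unit} for n, lm in ls.landmarks.items()
        },
    }


def landmarks_from_json(obj: dict) -> LandmarkSet:
    lms = {
        n: Landmark(n, float(v["x"]), float(v["y"]), v.get("unit", "mm"))
        for n, v in obj["landmarks"].items()
    }
    return LandmarkSet(
        subject_id=obj["subject_id"], landmarks=lms, scale=float(obj.get("scale", 1.0))
    )


def write_landmarks_json(ls: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks_to_json(ls), indent=2) + "\n")


def read_landmarks(path: str | Path, fmt: str | None = None, scale: float | None = None) -> list[LandmarkSet]:
    """Read landmark set(s), inferring the format from the suffix.

    ``scale`` overrides the file's mm-per-unit metadata when given.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "tps":
        sets = read_tps(path)
    elif fmt == "csv":
        sets = [read_landmarks_csv(path)]
    elif fmt == "json":
        sets = [landmarks_from_json(json.loads(path.read_text()))]
    else:
        raise FaceHarmonyError(f"unknown landmark format {fmt!r} for {path}")
    if scale is not None:
        sets = [
            LandmarkSet(subject_id=s.subject_id, landmarks=s.landmarks, scale=scale)
            for s in sets
        ]
    for s in sets:
        missing = [n for n in VOCABULARY if n not in s]
        if missing:
            raise MissingLandmarkError(missing[0], f"file {path}")
    return sets


# ---- analysis report -------------------------------------------------------


@dataclass
class SubjectResult:
    subject_id: str
    measurements: ProfileMeasurements
    classification: HarmonyClassification
    recommendations: list[str] = field(default_factory=list)
    angle_class: str | None = None


@dataclass
class AnalysisReport:
    """Per-subject results plus cohort tables, with provenance."""

    subjects: list[SubjectResult] = field(default_factory=list)
    cohort_prevalence: list[dict] | None = None
    cohort_exact_tests: dict[str, dict] | None = None
    config_hash: str = ""
    seed: int | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
            },
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "angle_class": s.angle_class,
                    "measurements": s.measurements.as_dict(),
                    "classification": s.classification.as_dict(),
                    "recommendations": s.recommendations,
                }
                for s in self.subjects
            ],
            "cohort": {
                "prevalence": self.cohort_prevalence,
                "exact_tests": self.cohort_exact_tests,
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisReport":
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        subjects = []
        for s in obj.get("subjects", []):
            cl = s["classification"]
            subjects.append(
                SubjectResult(
                    subject_id=s["subject_id"],
                    angle_class=s.get("angle_class"),
                    measurements=ProfileMeasurements(**s["measurements"]),
                    classification=HarmonyClassification(
                        vertical_category=cl["vertical"],
                        oli_category=cl["OLI"],
                        uli_category=cl["ULI"],
                        mi_category=cl["MI"],
                    ),
                    recommendations=list(s.get("recommendations", [])),
                )
            )
        prov = obj.get("provenance", {})
        cohort = obj.get("cohort", {})
        return cls(
            subjects=subjects,
            cohort_prevalence=cohort.get("prevalence"),
            cohort_exact_tests=cohort.get("exact_tests"),
            config_hash=prov.get("config_hash", ""),
            seed=prov.get("seed"),
            version=prov.get("version", __version__),
        )


# ---- pipeline --------------------------------------------------------------


def analyse_subject(
    ls: LandmarkSet,
    config: PipelineConfig | None = None,
    angle_class: str | None = None,
) -> SubjectResult:
    config = config or PipelineConfig()
    m = measure_profile(
        ls,
        structure_pairs=config.structure_pairs,
        val_angle_deg=config.val_angle_deg,
        val_rotation_sense=config.val_rotation_sense,
    )
    c = classify_profile(m, config.normative)
    recs = recommend_procedures(c, angle_class) if angle_class else []
    return SubjectResult(
        subject_id=ls.subject_id,
        measurements=m,
        classification=c,
        recommendations=recs,
        angle_class=angle_class,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    landmark_sets: list[LandmarkSet] | None = None,
    cohort: list[PatientRecord] | str | Path | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Measure -> classify -> (optional) cohort statistics.

    Deterministic given config and seed; any stage failure is re-raised
    as a :class:`PipelineError` naming the stage.
    """
    config = config or PipelineConfig()
    report = AnalysisReport(config_hash=config.hash(), seed=seed)

    if landmark_sets:
        for ls in landmark_sets:
            try:
                report.subjects.append(analyse_subject(ls, config))
            except FaceHarmonyError as e:
                raise PipelineError("measure/classify", f"subject {ls.subject_id!r}: {e}") from e

    if cohort is not None:
        try:
            records = cohort if isinstance(cohort, list) else read_cohort_csv(cohort)
            prev = prevalence_table(records)
            report.cohort_prevalence = prev.to_dict(orient="records")
            tests = {}
            for d in ("vertical", "OLI", "ULI", "MI"):
                ct = harmony_by_class_table(records, d)
                res = fisher_freeman_halton(ct)
                tests[d] = {
                    "p_value": res.p_value,
                    "p_display": format_p(res.p_value),
                    "table": ct.counts.tolist(),
                }
            report.cohort_exact_tests = tests
        except FaceHarmonyError as e:
            raise PipelineError("cohort-statistics", str(e)) from e
    return report
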