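"""Named 2D soft-tissue profile landmarks.

Coordinate convention used throughout the package: 2D Cartesian with x
anterior-positive and y superior-positive, so the subject faces the +x
half-plane, "caudal" is the -y direction, and ventral/dorsal deviations
are +x / -x.  Coordinates may be raw pixels or millimetres; a
``scale`` factor (mm per coordinate unit) converts lengths to mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidLandmarkSetError,
    MissingLandmarkError,
    UnknownLandmarkError,
)

#: Fixed landmark vocabulary, superior to inferior along the profile.
#: G glabella, N soft-tissue nasion, Prn pronasale, Sn subnasale,
#: Ls labrale superius, St stomion, Li labrale inferius,
#: Pg soft-tissue pogonion, Me soft-tissue menton.
VOCABULARY: tuple[str, ...] = ("G", "N", "Prn", "Sn", "Ls", "St", "Li", "Pg", "Me")

#: Landmarks that must satisfy strict superior-to-inferior ordering in y.
ORDERING_CHAIN: tuple[str, ...] = ("N", "Sn", "St", "Me")

VALID_UNITS = ("pixel", "mm")


@dataclass(frozen=True)
class Landmark:
    """A single named profile point."""

    name: str
    x: float
    y: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.name not in VOCABULARY:
            raise UnknownLandmarkError(
                f"unknown landmark name {self.name!r}; expected one of {VOCABULARY}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidLandmarkSetError(
                f"landmark {self.name!r} has non-finite coordinates ({self.x}, {self.y})"
            )
        if self.unit not in VALID_UNITS:
            raise InvalidLandmarkSetError(
                f"landmark {self.name!r} has unknown unit {self.unit!r}"
            )

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class LandmarkSet:
    """All profile landmarks of one subject plus scale metadata.

    Parameters
    ----------
    subject_id:
        Free-form identifier.
    landmarks:
        Mapping from landmark name to :class:`Landmark`.
    scale:
        Millimetres per coordinate unit (1.0 when coordinates are mm).
    """

    subject_id: str
    landmarks: dict[str, Landmark] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise InvalidLandmarkSetError(f"scale must be positive, got {self.scale}")
        for name in self.landmarks:
            if name not in VOCABULARY:
                raise UnknownLandmarkError(
                    f"unknown landmark name {name!r}; expected one of {VOCABULARY}"
                )

    @classmethod
    def from_coords(
        cls,
        subject_id: str,
        coords: Mapping[str, tuple[float, float]],
        scale: float = 1.0,
        unit: str = "mm",
    ) -> "LandmarkSet":
        lms = {n: Landmark(n, float(x), float(y), unit) for n, (x, y) in coords.items()}
        return cls(subject_id=subject_id, landmarks=lms, scale=scale)

    def __contains__(self, name: str) -> bool:
        return name in self.landmarks

    def __getitem__(self, name: str) -> np.ndarray:
        """Coordinates of a landmark as an (x, y) array."""
        try:
            return self.landmarks[name].xy
        except KeyError:
            raise MissingLandmarkError(name, f"subject {self.subject_id!r}") from None

    def require(self, names: Iterable[str]) -> None:
        for n in names:
            if n not in self.landmarks:
                raise MissingLandmarkError(n, f"subject {self.subject_id!r}")

    @property
    def is_complete(self) -> bool:
        return all(n in self.landmarks for n in VOCABULARY)

    def validate_full(self) -> None:
        """Check completeness and the superior-to-inferior ordering invariant.

        A full analysis requires all nine vocabulary landmarks and
        y(N) > y(Sn) > y(St) > y(Me).
        """
        self.require(VOCABULARY)
        ys = [self.landmarks[n].y for n in ORDERING_CHAIN]
        for (a, b, ya, yb) in zip(ORDERING_CHAIN, ORDERING_CHAIN[1:], ys, ys[1:]):
            if not ya > yb:
                raise InvalidLandmarkSetError(
                    f"ordering violated for subject {self.subject_id!r}: "
                    f"y({a})={ya} must exceed y({b})={yb}"
                )

    def transformed(
        self,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        scale_factor: float = 1.0,
        new_scale: float | None = None,
    ) -> "LandmarkSet":
        """Apply a similarity transform (rotate, scale, translate) to all points.

        ``new_scale`` overrides the mm-per-unit metadata of the result; by
        default the metadata scale is left unchanged (so a pure rigid
        transform preserves mm measurements).
        """
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        t = np.asarray(translation, dtype=float)
        out = {}
        for name, lm in self.landmarks.items():
            p = scale_factor * (rot @ lm.xy) + t
            out[name] = Landmark(name, float(p[0]), float(p[1]), lm.unit)
        return LandmarkSet(
            subject_id=self.subject_id,
            landmarks=out,
            scale=self.scale if new_scale is None else new_scale,
        )


def calibrate_scale(
    p1: tuple[float, float] | np.ndarray,
    p2: tuple[float, float] | np.ndarray,
    known_mm: float,
) -> float:
    """Millimetres per coordinate unit from a segment of known physical length.

    Generalises a print-at-1:1 assumption: given two image points a known
    distance apart (e.g. the ends of a ruler in frame), returns the factor
    that converts raw coordinate distances to mm.
    """
    if not known_mm > 0:
        raise InvalidLandmarkSetError(f"known_mm must be positive, got {known_mm}")
    d = float(np.linalg.norm(np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)))
    if d == 0.0:
        raise DegenerateGeometryError("calibration points coincide")
    return known_mm / d
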