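"""Construction lines and the seven profile measurements.

The analysis draws two lines on the profile: the nasofrontal line (NFL)
through glabella and soft-tissue nasion, and the vertical analysis line
(VAL), obtained by rotating the NFL by 15 degrees about nasion so that
its caudal end moves posteriorly.  Facial heights are scalar projections
of inter-landmark vectors onto the VAL direction; inclinations are signed
angles between the VAL and anatomical structure lines, positive when the
structure's caudal end lies anterior (ventral) to the VAL.

Measurements
------------
NasFH, MaxFH, MandFH : mm
    Nasofacial (N-Sn), maxillofacial (Sn-St) and mandibulofacial (St-Me)
    heights along the VAL.
NRI, OLI, ULI, MI : degrees
    Nasal-bridge (N-Prn), upper-lip (Sn-Ls), lower-lip (St-Li) and
    mandibular/chin (St-Pg) inclinations relative to the VAL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegenerateGeometryError, InvalidMeasurementError
from .landmarks import LandmarkSet

VAL_ANGLE_DEG = 15.0

#: Landmark pairs defining each structure line, superior point first.
#: These pairs are configuration, not anatomy fixed by the method itself.
DEFAULT_STRUCTURE_PAIRS: dict[str, tuple[str, str]] = {
    "NRI": ("N", "Prn"),
    "OLI": ("Sn", "Ls"),
    "ULI": ("St", "Li"),
    "MI": ("St", "Pg"),
}


@dataclass(frozen=True)
class Line:
    """An oriented line: anchor point plus caudal unit direction.

    The direction always points toward the -y half-plane (caudally), so
    signed angles between lines are well defined.
    """

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.all(np.isfinite(d)):
            raise DegenerateGeometryError("line direction is degenerate")
        d = d / n
        if d[1] > 1e-12:
            raise DegenerateGeometryError(
                f"line direction must point caudally (y <= 0), got {tuple(d)}"
            )
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction


@dataclass(frozen=True)
class ProfileMeasurements:
    """The seven profile quantities: three heights (mm), four angles (deg)."""

    NasFH: float
    MaxFH: float
    MandFH: float
    NRI: float
    OLI: float
    ULI: float
    MI: float

    def __post_init__(self) -> None:
        for h in ("NasFH", "MaxFH", "MandFH"):
            if getattr(self, h) < 0:
                raise InvalidMeasurementError(f"{h} must be >= 0")
        for a in ("NRI", "OLI", "ULI", "MI"):
            v = getattr(self, a)
            if not -90.0 < v < 90.0:
                raise InvalidMeasurementError(f"{a}={v} outside (-90, 90) degrees")

    @property
    def heights(self) -> tuple[float, float, float]:
        return (self.NasFH, self.MaxFH, self.MandFH)

    @property
    def angles(self) -> tuple[float, float, float, float]:
        return (self.NRI, self.OLI, self.ULI, self.MI)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("NasFH", "MaxFH", "MandFH", "NRI", "OLI", "ULI", "MI")}


def _structure_direction(p_sup: np.ndarray, p_inf: np.ndarray) -> np.ndarray:
    # pairs are given superior landmark first, so this direction is caudal
    # in anatomical orientation and co-rotates with the landmark set
    d = np.asarray(p_inf, dtype=float) - np.asarray(p_sup, dtype=float)
    if np.linalg.norm(d) == 0:
        raise DegenerateGeometryError("structure line endpoints coincide")
    return d / np.linalg.norm(d)


def construct_nfl(landmarks: LandmarkSet) -> Line:
    """Nasofrontal line through glabella (G) and nasion (N), anchored at N.

    G must lie strictly superior to N; the direction runs caudally from G
    through N.
    """
    landmarks.require(("G", "N"))
    g, n = landmarks["G"], landmarks["N"]
    if np.allclose(g, n):
        raise DegenerateGeometryError("G and N coincide; NFL undefined")
    if not g[1] > n[1]:
        raise DegenerateGeometryError("G must be strictly superior to N")
    return Line(anchor=n, direction=n - g)


def construct_val(
    nfl: Line,
    anchor: np.ndarray,
    angle_deg: float = VAL_ANGLE_DEG,
    rotation_sense: str = "posterior",
) -> Line:
    """Vertical analysis line: NFL rotated by ``angle_deg`` about nasion.

    With the default ``rotation_sense="posterior"`` the caudal end of the
    direction moves toward -x (dorsally); ``"anterior"`` rotates the other
    way.  The sense is configurable because the construction is stated as
    a rotation magnitude only.
    """
    th = math.radians(angle_deg)
    if rotation_sense == "posterior":
        th = -th  # clockwise for a caudal-pointing direction moves it to -x
    elif rotation_sense != "anterior":
        raise ValueError(f"rotation_sense must be 'posterior' or 'anterior', got {rotation_sense!r}")
    c, s = math.cos(th), math.sin(th)
    d = nfl.direction
    rotated = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
    return Line(anchor=np.asarray(anchor, dtype=float), direction=rotated)


def signed_angle_deg(reference: np.ndarray, other: np.ndarray) -> float:
    """Signed angle (degrees) from ``reference`` to ``other``.

    For two caudal (downward) unit directions the sign is positive when
    ``other``'s caudal end lies anterior (+x) of ``reference``.
    """
    r = np.asarray(reference, dtype=float)
    o = np.asarray(other, dtype=float)
    cross = r[0] * o[1] - r[1] * o[0]
    dot = float(r @ o)
    return math.degrees(math.atan2(cross, dot))


def measure_heights(
    landmarks: LandmarkSet, val: Line
) -> tuple[float, float, float]:
    """NasFH, MaxFH, MandFH in mm: projections of N-Sn, Sn-St, St-Me onto VAL.

    Using scalar projections onto the single VAL axis (rather than raw
    Euclidean distances) keeps the three heights commensurable; the sum of
    the three equals the N-Me projection.
    """
    landmarks.require(("N", "Sn", "St", "Me"))
    d = val.direction
    seg = [("N", "Sn"), ("Sn", "St"), ("St", "Me")]
    out = []
    for a, b in seg:
        proj = float((landmarks[b] - landmarks[a]) @ d)
        out.append(abs(proj) * landmarks.scale)
    return tuple(out)  # type: ignore[return-value]


def measure_inclinations(
    landmarks: LandmarkSet,
    val: Line,
    structure_pairs: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[float, float, float, float]:
    """NRI, OLI, ULI, MI in degrees: signed angles of structure lines vs VAL.

    Positive angles are ventral (structure's caudal end anterior to the
    VAL), negative dorsal.
    """
    pairs = dict(DEFAULT_STRUCTURE_PAIRS)
    if structure_pairs:
        pairs.update(structure_pairs)
    out = []
    for key in ("NRI", "OLI", "ULI", "MI"):
        sup, inf = pairs[key]
        landmarks.require((sup, inf))
        d = _structure_direction(landmarks[sup], landmarks[inf])
        out.append(signed_angle_deg(val.direction, d))
    return tuple(out)  # type: ignore[return-value]


def measure_profile(
    landmarks: LandmarkSet,
    structure_pairs: Mapping[str, tuple[str, str]] | None = None,
    val_angle_deg: float = VAL_ANGLE_DEG,
    val_rotation_sense: str = "posterior",
) -> ProfileMeasurements:
    """Full measurement pipeline: NFL -> VAL -> heights + inclinations."""
    landmarks.validate_full()
    nfl = construct_nfl(landmarks)
    val = construct_val(
        nfl, landmarks["N"], angle_deg=val_angle_deg, rotation_sense=val_rotation_sense
    )
    nasfh, maxfh, mandfh = measure_heights(landmarks, val)
    nri, oli, uli, mi = measure_inclinations(landmarks, val, structure_pairs)
    return ProfileMeasurements(
        NasFH=nasfh, MaxFH=maxfh, MandFH=mandfh, NRI=nri, OLI=oli, ULI=uli, MI=mi
    )
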