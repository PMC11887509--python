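"""Normative bands for the profile measurements.

The vertical norm derives the optimal mandibulofacial height from the
golden section of the measured upper-face heights; the sagittal norms are
bands around a centre that depends linearly on the nasal-bridge
inclination.  Every constant here is a configuration key: the default
vertical rule is MandFH_opt = phi * MaxFH with a +/-10 % band, and the
default sagittal rules (centre = 0.5 * NRI, halfwidth 5 deg) are
placeholder coefficients with the same override contract, so an
authoritative set of published coefficients can be dropped in from a
config file without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .errors import InvalidMeasurementError

GOLDEN_RATIO = 1.6180339887

SAGITTAL_PARAMS = ("OLI", "ULI", "MI")

#: Named vertical rules mapping (NasFH, MaxFH, phi) -> MandFH_opt.
VERTICAL_RULES: dict[str, Callable[[float, float, float], float]] = {
    # golden section of the lower face at stomion: MandFH / MaxFH = phi
    "phi_times_maxfh": lambda nasfh, maxfh, phi: phi * maxfh,
    # alternative reading: lower face mirrors the nose length
    "nasfh_identity": lambda nasfh, maxfh, phi: nasfh,
}


@dataclass(frozen=True)
class SagittalRule:
    """Band centre = intercept + slope * NRI; band = centre -/+ halfwidth."""

    intercept: float = 0.0
    slope: float = 0.5
    halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if not self.halfwidth > 0:
            raise InvalidMeasurementError(
                f"sagittal halfwidth must be positive, got {self.halfwidth}"
            )

    def band(self, nri: float) -> tuple[float, float]:
        centre = self.intercept + self.slope * nri
        return (centre - self.halfwidth, centre + self.halfwidth)


@dataclass(frozen=True)
class NormativeModel:
    """Fully config-overridable normative model.

    Attributes
    ----------
    phi:
        Golden-ratio constant used by the vertical rule.
    vertical_rule:
        Name of a rule in :data:`VERTICAL_RULES`, or a custom callable
        ``(NasFH, MaxFH, phi) -> MandFH_opt`` assigned via
        :meth:`with_vertical_rule`.
    band_fraction:
        Half-width of the vertical normal range as a fraction of
        MandFH_opt (0.10 -> limits at 90 % and 110 % of the optimum).
    sagittal:
        Per-angle affine band rules keyed by OLI/ULI/MI.
    boundary_policy:
        "inclusive" (values exactly on a limit are in range) is the only
        implemented policy; recorded in config for explicitness.
    """

    phi: float = GOLDEN_RATIO
    vertical_rule: str = "phi_times_maxfh"
    band_fraction: float = 0.10
    sagittal: dict[str, SagittalRule] = field(
        default_factory=lambda: {p: SagittalRule() for p in SAGITTAL_PARAMS}
    )
    boundary_policy: str = "inclusive"
    _vertical_callable: Callable[[float, float, float], float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.band_fraction < 1:
            raise InvalidMeasurementError(
                f"band_fraction must lie in (0, 1), got {self.band_fraction}"
            )
        if self._vertical_callable is None and self.vertical_rule not in VERTICAL_RULES:
            raise InvalidMeasurementError(
                f"unknown vertical rule {self.vertical_rule!r}; "
                f"known: {sorted(VERTICAL_RULES)}"
            )
        if self.boundary_policy != "inclusive":
            raise InvalidMeasurementError(
                f"unsupported boundary policy {self.boundary_policy!r}"
            )
        missing = set(SAGITTAL_PARAMS) - set(self.sagittal)
        if missing:
            raise InvalidMeasurementError(f"sagittal rules missing for {sorted(missing)}")

    def with_vertical_rule(
        self, rule: Callable[[float, float, float], float], name: str = "custom"
    ) -> "NormativeModel":
        return replace(self, vertical_rule=name, _vertical_callable=rule)

    def mandfh_opt(self, nasfh: float, maxfh: float) -> float:
        fn = self._vertical_callable or VERTICAL_RULES[self.vertical_rule]
        return fn(nasfh, maxfh, self.phi)

    # ---- config round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phi": self.phi,
            "vertical": {"rule": self.vertical_rule, "band_fraction": self.band_fraction},
            "sagittal": {
                p: {"intercept": r.intercept, "slope": r.slope, "halfwidth": r.halfwidth}
                for p, r in self.sagittal.items()
            },
            "boundary_policy": self.boundary_policy,
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "NormativeModel":
        sag = {
            p: SagittalRule(**{k: float(v) for k, v in spec.items()})
            for p, spec in cfg.get("sagittal", {}).items()
        }
        for p in SAGITTAL_PARAMS:
            sag.setdefault(p, SagittalRule())
        vert = cfg.get("vertical", {})
        return cls(
            phi=float(cfg.get("phi", GOLDEN_RATIO)),
            vertical_rule=vert.get("rule", "phi_times_maxfh"),
            band_fraction=float(vert.get("band_fraction", 0.10)),
            sagittal=sag,
            boundary_policy=cfg.get("boundary_policy", "inclusive"),
        )


def vertical_band(
    nasfh: float, maxfh: float, model: NormativeModel | None = None
) -> tuple[float, float, float]:
    """(MandFH_opt, SF_limit, LF_limit) for measured NasFH and MaxFH (mm).

    Below SF_limit the lower face is a short-face configuration, above
    LF_limit a long-face configuration; the limits strictly bracket the
    optimum.
    """
    model = model or NormativeModel()
    if not (nasfh > 0 and maxfh > 0):
        raise InvalidMeasurementError(
            f"heights must be positive, got NasFH={nasfh}, MaxFH={maxfh}"
        )
    opt = model.mandfh_opt(nasfh, maxfh)
    if not opt > 0:
        raise InvalidMeasurementError(f"vertical rule produced non-positive optimum {opt}")
    lo = (1.0 - model.band_fraction) * opt
    hi = (1.0 + model.band_fraction) * opt
    return (opt, lo, hi)


def sagittal_band(
    param: str, nri: float, model: NormativeModel | None = None
) -> tuple[float, float]:
    """(low, high) band in degrees for OLI/ULI/MI at a given NRI."""
    model = model or NormativeModel()
    if param not in SAGITTAL_PARAMS:
        raise InvalidMeasurementError(
            f"unknown sagittal parameter {param!r}; expected one of {SAGITTAL_PARAMS}"
        )
    return model.sagittal[param].band(nri)
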