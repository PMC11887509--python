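"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction
from math import factorial

import numpy as np
import pytest

from faceharmony.landmarks import LandmarkSet
from faceharmony.synth import Deformation, generate_profile, profile_template

# ---- independent geometry oracle ------------------------------------------
# Closed-form angle arithmetic (atan2 of coordinate differences), written
# deliberately without the package's Line/rotation-matrix machinery.


def oracle_profile(coords: dict[str, tuple[float, float]], scale: float = 1.0) -> dict[str, float]:
    gx, gy = coords["G"]
    nx, ny = coords["N"]
    # angle of the caudal NFL direction, measured from straight down,
    # anterior positive
    nfl_ang = math.atan2(nx - gx, gy - ny)
    val_ang = nfl_ang - math.radians(15.0)  # posterior rotation
    ux, uy = math.sin(val_ang), -math.cos(val_ang)

    def height(a: str, b: str) -> float:
        dx = coords[b][0] - coords[a][0]
        dy = coords[b][1] - coords[a][1]
        return abs(dx * ux + dy * uy) * scale

    def incl(a: str, b: str) -> float:
        dx = coords[b][0] - coords[a][0]
        dy = coords[b][1] - coords[a][1]
        return math.degrees(math.atan2(dx, -dy) - val_ang)

    return {
        "NasFH": height("N", "Sn"),
        "MaxFH": height("Sn", "St"),
        "MandFH": height("St", "Me"),
        "NRI": incl("N", "Prn"),
        "OLI": incl("Sn", "Ls"),
        "ULI": incl("St", "Li"),
        "MI": incl("St", "Pg"),
    }


# ---- independent exact-test oracle -----------------------------------------
# Exact rational arithmetic over nested loops on the two free cells of a
# 3x2 table; immune to floating-point ties by construction.


def oracle_freeman_halton_3x2(table) -> Fraction:
    rm = [sum(r) for r in table]
    cm = [sum(c) for c in zip(*table)]
    n = sum(rm)
    const = Fraction(1)
    for r in rm:
        const *= factorial(r)
    for c in cm:
        const *= factorial(c)
    const = Fraction(const, factorial(n))

    def prob(t) -> Fraction:
        den = 1
        for row in t:
            for x in row:
                den *= factorial(x)
        return const / den

    p_obs = prob(table)
    total = Fraction(0)
    p_sum = Fraction(0)
    for a in range(min(rm[0], cm[0]) + 1):
        for b in range(min(rm[1], cm[0] - a) + 1):
            c0 = cm[0] - a - b
            if c0 > rm[2]:
                continue
            t = [[a, rm[0] - a], [b, rm[1] - b], [c0, rm[2] - c0]]
            p = prob(t)
            total += p
            if p <= p_obs:
                p_sum += p
    assert total == 1, "enumerated probabilities must sum to exactly 1"
    return p_sum


# ---- random landmark configurations ----------------------------------------


def random_profiles(n: int, seed: int, max_noise: float = 0.8):
    """Deformed, noisy, similarity-transformed valid landmark sets."""
    rng = np.random.default_rng(seed)
    out: list[LandmarkSet] = []
    while len(out) < n:
        d = Deformation(
            mandible_shift_mm=float(rng.uniform(-4, 4)),
            maxilla_shift_mm=float(rng.uniform(-4, 4)),
            elongation=float(rng.uniform(-0.15, 0.25)),
        )
        try:
            ls = generate_profile(
                profile_template(f"rand{len(out)}"),
                deformation=d,
                noise_sd=float(rng.uniform(0, max_noise)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except Exception:
            continue
        out.append(
            ls.transformed(
                rotation_deg=float(rng.uniform(-20, 20)),
                translation=(float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50))),
            )
        )
    return out


@pytest.fixture
def template() -> LandmarkSet:
    return profile_template()


@pytest.fixture
def margin_cohort():
    from faceharmony.reference_cohort import margin_matched_cohort

    return margin_matched_cohort()
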