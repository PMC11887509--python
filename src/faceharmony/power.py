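"""Monte-Carlo power of the two-sided Fisher exact test for two proportions.

Models the cohort comparison as two independent binomial groups whose
success probabilities differ by a fixed odds ratio: given a baseline
prevalence p1, the second group has odds OR * p1/(1-p1).  Power is the
fraction of simulated datasets with a two-sided Fisher exact p-value
below alpha, with a binomial Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import fisher_exact

from .errors import InvalidMeasurementError


@dataclass(frozen=True)
class PowerResult:
    power: float
    se: float
    reps: int
    alpha: float
    odds_ratio: float
    n_per_group: int
    baseline_prevalence: float
    shifted_prevalence: float


def shifted_prevalence(baseline: float, odds_ratio: float) -> float:
    """Second-group prevalence implied by the odds ratio."""
    if not 0 < baseline < 1:
        raise InvalidMeasurementError(f"baseline prevalence {baseline} outside (0, 1)")
    odds = odds_ratio * baseline / (1 - baseline)
    p2 = odds / (1 + odds)
    if not 0 < p2 < 1:
        raise InvalidMeasurementError(
            f"odds ratio {odds_ratio} pushes prevalence out of (0, 1)"
        )
    return p2


@lru_cache(maxsize=200_000)
def _fisher_p(x1: int, x2: int, n1: int, n2: int) -> float:
    # binomial draws repeat heavily, so memoise by the observed counts
    return float(fisher_exact([[x1, n1 - x1], [x2, n2 - x2]]).pvalue)


def power_fisher_sim(
    alpha: float,
    odds_ratio: float,
    n_per_group: int,
    baseline_prevalence: float,
    reps: int,
    seed: int,
) -> PowerResult:
    """Simulated power of the Fisher exact test at a given odds ratio.

    ``reps`` independent pairs of binomial groups are drawn; each is
    tested two-sided and compared against ``alpha``.  Reproducible for a
    fixed seed.
    """
    if not 0 < alpha < 1:
        raise InvalidMeasurementError(f"alpha {alpha} outside (0, 1)")
    if reps < 1000:
        raise InvalidMeasurementError(f"need reps >= 1000 for a stable estimate, got {reps}")
    p2 = shifted_prevalence(baseline_prevalence, odds_ratio)
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n_per_group, baseline_prevalence, size=reps)
    x2 = rng.binomial(n_per_group, p2, size=reps)
    hits = sum(
        _fisher_p(int(a), int(b), n_per_group, n_per_group) < alpha
        for a, b in zip(x1, x2)
    )
    power = hits / reps
    se = float(np.sqrt(power * (1 - power) / reps))
    return PowerResult(
        power=power,
        se=se,
        reps=reps,
        alpha=alpha,
        odds_ratio=odds_ratio,
        n_per_group=n_per_group,
        baseline_prevalence=baseline_prevalence,
        shifted_prevalence=p2,
    )
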