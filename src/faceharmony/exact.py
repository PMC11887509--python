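"""Freeman–Halton exact test of independence for r x c count tables.

The test generalises Fisher's 2x2 exact test: conditioning on both
margins, the probability of a table is multivariate hypergeometric,

    P(T) = (prod_i r_i!) (prod_j c_j!) / ( N! prod_ij n_ij! ),

and the two-sided p-value is the total probability of all tables with
the observed margins whose probability does not exceed that of the
observed table.  Enumeration is exact (no asymptotics); a small additive
tie tolerance absorbs floating-point near-ties among tables whose
probabilities are mathematically equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateMarginError, InvalidMeasurementError

#: Additive tolerance on table probability when comparing against the
#: observed table's probability (absorbs float near-ties).
TIE_TOL = 1e-7


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
            raise InvalidMeasurementError(
                f"contingency table must be at least 2x2, got shape {a.shape}"
            )
        if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)) or np.any(a < 0):
                raise InvalidMeasurementError("counts must be non-negative integers")
        self.counts = a.astype(np.int64)
        if not self.row_labels:
            self.row_labels = tuple(f"r{i}" for i in range(a.shape[0]))
        if not self.col_labels:
            self.col_labels = tuple(f"c{j}" for j in range(a.shape[1]))

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ExactTestResult:
    """Outcome of the exact enumeration.

    ``total_probability`` sums the probabilities of every enumerated
    table; it equals 1 up to rounding and is kept as a self-check.
    """

    p_value: float
    observed_probability: float
    n_tables: int
    total_probability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise InvalidMeasurementError(f"p-value {self.p_value} outside (0, 1]")
        if self.p_value < self.observed_probability - 1e-12:
            raise InvalidMeasurementError(
                "p-value cannot be smaller than the observed table probability"
            )


def _log_table_prob(flat: np.ndarray, log_const: float, lgamma: np.ndarray) -> float:
    return log_const - float(lgamma[flat + 1].sum())


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray):
    """Yield every non-negative integer table with the given margins.

    Rows are filled recursively; within a row, cells are filled left to
    right bounded by the remaining column capacity.  The last row and the
    last cell of each row are forced, which keeps the search tree tight.
    """
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)
    rem_cols = col_margins.astype(np.int64).copy()

    def fill_row(i: int):
        if i == r - 1:
            # last row forced by remaining column margins
            if rem_cols.min() >= 0 and rem_cols.sum() == row_margins[i]:
                table[i, :] = rem_cols
                yield table
            return

        row_total = int(row_margins[i])

        def fill_cell(j: int, remaining: int):
            if j == c - 1:
                if remaining <= rem_cols[j]:
                    table[i, j] = remaining
                    rem_cols[j] -= remaining
                    yield from fill_row(i + 1)
                    rem_cols[j] += remaining
                return
            # lower bound keeps later cells feasible
            later_capacity = int(rem_cols[j + 1 :].sum())
            lo = max(0, remaining - later_capacity)
            hi = min(remaining, int(rem_cols[j]))
            for v in range(lo, hi + 1):
                table[i, j] = v
                rem_cols[j] -= v
                yield from fill_cell(j + 1, remaining - v)
                rem_cols[j] += v

        yield from fill_cell(0, row_total)

    yield from fill_row(0)


def fisher_freeman_halton(table: ContingencyTable | np.ndarray) -> ExactTestResult:
    """Exact two-sided test of independence for an r x c table.

    For 2x2 input this reproduces the classical two-sided Fisher exact
    p-value.  All margins must be positive.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    rm, cm = table.row_margins, table.col_margins
    if rm.min() <= 0 or cm.min() <= 0:
        raise DegenerateMarginError(
            f"all margins must be positive; row margins {rm.tolist()}, "
            f"column margins {cm.tolist()}"
        )
    n = table.total
    lgamma = gammaln(np.arange(n + 2, dtype=float))
    log_const = float(lgamma[rm + 1].sum() + lgamma[cm + 1].sum() - lgamma[n + 1])

    obs_flat = table.counts.ravel()
    log_p_obs = _log_table_prob(obs_flat, log_const, lgamma)
    p_obs = float(np.exp(log_p_obs))

    p_sum = 0.0
    total = 0.0
    count = 0
    threshold = p_obs + TIE_TOL
    for t in _enumerate_tables(rm, cm):
        lp = _log_table_prob(t.ravel(), log_const, lgamma)
        p = float(np.exp(lp))
        total += p
        count += 1
        if p <= threshold:
            p_sum += p
    return ExactTestResult(
        p_value=min(p_sum, 1.0),
        observed_probability=p_obs,
        n_tables=count,
        total_probability=total,
    )


def format_p(p: float, decimals: int = 3) -> str:
    """Render a p-value at table precision, with '< 0.001' below it."""
    floor = 10.0 ** (-decimals)
    if p < floor:
        return f"< {floor:.{decimals}f}"
    return f"{p:.{decimals}f}"
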