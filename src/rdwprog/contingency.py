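"""Association tests between trajectory class and mortality.

Pearson chi-square (no continuity correction), the two-sided 2x2 Fisher
exact test (point-probability rule: sum of same-margin tables whose
hypergeometric probability does not exceed the observed table's), and its
R x C generalisation by full enumeration or seeded Monte-Carlo sampling
from the margin-conditional null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateMarginError, EnumerationBoundError

#: relative tolerance when comparing table point probabilities
_LOGP_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """R x C grid of non-negative integer counts with labelled margins."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise DegenerateMarginError("need at least a 2x2 table")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise DegenerateMarginError("counts must be non-negative integers")
        if arr.sum() == 0:
            raise DegenerateMarginError("table total must be positive")
        if self.row_labels and len(self.row_labels) != arr.shape[0]:
            raise DegenerateMarginError("row_labels length mismatch")
        if self.col_labels and len(self.col_labels) != arr.shape[1]:
            raise DegenerateMarginError("col_labels length mismatch")

    @classmethod
    def from_array(cls, counts, row_labels=(), col_labels=()) -> "ContingencyTable":
        arr = np.asarray(counts)
        if not np.all(arr == np.rint(arr)):
            raise DegenerateMarginError("counts must be integers")
        return cls(
            counts=tuple(tuple(int(v) for v in row) for row in arr),
            row_labels=tuple(row_labels),
            col_labels=tuple(col_labels),
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.to_array()
    return ContingencyTable.from_array(table).to_array()


def _check_margins(arr: np.ndarray) -> None:
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise DegenerateMarginError("table has an all-zero row or column margin")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    arr = _as_array(table)
    _check_margins(arr)
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


@dataclass(frozen=True)
class FisherResult:
    p: float
    degenerate: bool = False


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided 2x2 Fisher exact test (point-probability rule).

    A table with a zero margin carries no information about association;
    by convention p = 1 with the degenerate flag set.
    """
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise DegenerateMarginError(f"expected a 2x2 table, got {arr.shape}")
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        return FisherResult(p=1.0, degenerate=True)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(p=float(min(p, 1.0)))


def _log_point_prob(arr: np.ndarray, lgf: np.ndarray) -> float:
    """log multivariate-hypergeometric probability of one same-margin table."""
    r = arr.sum(axis=1)
    c = arr.sum(axis=0)
    n = arr.sum()
    return float(lgf[r].sum() + lgf[c].sum() - lgf[n] - lgf[arr].sum())


def count_tables(row_margins: Sequence[int], col_margins: Sequence[int],
                 bound: int = 10**7) -> int:
    """Number of non-negative integer tables with the given margins,
    counted by the same recursion the exact test uses (stops at bound)."""
    counter = [0]
    for _ in _iter_tables(np.asarray(row_margins), np.asarray(col_margins), bound,
                          counter):
        pass
    return counter[0]


def _iter_tables(rows: np.ndarray, cols: np.ndarray, bound: int, counter: list):
    """Yield every table with the given margins, row by row (depth-first)."""
    R, C = len(rows), len(cols)
    table = np.zeros((R, C), dtype=np.int64)

    def fill(i: int, col_rem: np.ndarray):
        if i == R - 1:
            # last row forced by the column remainders
            if np.all(col_rem >= 0) and col_rem.sum() == rows[i]:
                table[i] = col_rem
                counter[0] += 1
                if counter[0] > bound:
                    raise EnumerationBoundError(
                        f"more than {bound} tables share these margins; "
                        "use method='monte_carlo'"
                    )
                yield table
            return
        yield from fill_row(i, 0, rows[i], col_rem)

    def fill_row(i: int, j: int, row_rem: int, col_rem: np.ndarray):
        if j == C - 1:
            if 0 <= row_rem <= col_rem[j]:
                table[i, j] = row_rem
                new_rem = col_rem.copy()
                new_rem[j] -= row_rem
                yield from fill(i + 1, new_rem)
            return
        tail = col_rem[j + 1:].sum()
        lo = max(0, row_rem - tail)
        hi = min(row_rem, col_rem[j])
        for x in range(lo, hi + 1):
            table[i, j] = x
            new_rem = col_rem.copy()
            new_rem[j] -= x
            yield from fill_row(i, j + 1, row_rem - x, new_rem)

    yield from fill(0, cols.astype(np.int64).copy())


def _sample_table(rng: np.random.Generator, rows: np.ndarray,
                  cols: np.ndarray) -> np.ndarray:
    """One draw from the margin-conditional (multivariate hypergeometric)
    null distribution, filled row by row."""
    R = len(rows)
    out = np.zeros((R, len(cols)), dtype=np.int64)
    col_rem = cols.astype(np.int64).copy()
    for i in range(R - 1):
        draw = rng.multivariate_hypergeometric(col_rem, int(rows[i]))
        out[i] = draw
        col_rem -= draw
    out[R - 1] = col_rem
    return out


def fisher_exact_rxc(
    table,
    method: str = "exact",
    n_mc: int = 100_000,
    seed: int | None = None,
    max_tables: int = 10**7,
) -> FisherResult:
    """R x C Fisher exact test by enumeration or Monte-Carlo.

    Exact mode sums the conditional probabilities of every same-margin
    table whose point probability is at or below the observed one,
    aborting with a pointer to Monte-Carlo if more than ``max_tables``
    tables share the margins. Monte-Carlo mode reports
    (1 + #{as-or-less-probable samples}) / (1 + n_mc), seeded and
    reproducible.
    """
    arr = _as_array(table)
    _check_margins(arr)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    lgf = gammaln(np.arange(int(arr.sum()) + 2) + 1.0)
    logp_obs = _log_point_prob(arr, lgf)
    cutoff = logp_obs + _LOGP_TOL

    if method == "exact":
        counter = [0]
        total = 0.0
        for t in _iter_tables(rows, cols, max_tables, counter):
            lp = lgf[rows].sum() + lgf[cols].sum() - lgf[arr.sum()] - lgf[t].sum()
            if lp <= cutoff:
                total += np.exp(lp)
        return FisherResult(p=float(min(total, 1.0)))
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        hits = 0
        const = lgf[rows].sum() + lgf[cols].sum() - lgf[arr.sum()]
        for _ in range(n_mc):
            t = _sample_table(rng, rows, cols)
            if const - lgf[t].sum() <= cutoff:
                hits += 1
        return FisherResult(p=float((hits + 1) / (n_mc + 1)))
    raise ValueError(f"method must be 'exact' or 'monte_carlo', got {method!r}")


def late_direction_table(deaths_up: int, total_up: int,
                         deaths_down: int, total_down: int) -> ContingencyTable:
    """2x2 table comparing late-upward vs late-downward trajectory mortality."""
    return ContingencyTable.from_array(
        [[deaths_up, total_up - deaths_up], [deaths_down, total_down - deaths_down]],
        row_labels=("late_up", "late_down"),
        col_labels=("died", "survived"),
    )
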