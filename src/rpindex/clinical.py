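"""Screening of non-genetic factors against the grade >=2 pneumonitis endpoint.

Categorical factors are tested with the two-sided Fisher exact test, continuous
factors with the Mann-Whitney U test, one factor at a time with no multiplicity
adjustment.  The two-sided Fisher p-value follows the point-probability
convention (as in R's ``fisher.test``): the sum of the probabilities, under the
fixed-margins (multivariate) hypergeometric null, of every table whose point
probability does not exceed that of the observed table, with a 1+1e-7 relative
guard on the comparison.  r x c tables are handled by exhaustive enumeration
over the free cells, with an explicit capacity error rather than a silent
approximation when the enumeration would be too large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

from .datatypes import CONTINUOUS_COVARIATES, ValidationError, validate_phenotypes

__all__ = ["fisher_exact", "mann_whitney_u", "screen_factors", "CapacityError"]


class CapacityError(RuntimeError):
    """The exact enumeration would exceed the configured table budget."""


_REL_TOL = 1.0 + 1e-7


def _log_table_prob(table: np.ndarray, row_margins: np.ndarray, col_margins: np.ndarray, n: int) -> float:
    const = gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum() - gammaln(n + 1)
    return float(const - gammaln(table + 1).sum())


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray):
    """Yield every nonnegative integer table with the given margins."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, j: int, row_left: np.ndarray, col_left: np.ndarray):
        if i == r - 1:
            # last row forced by column margins
            if (col_left >= 0).all():
                table[r - 1] = col_left
                yield table
            return
        if j == c - 1:
            # last cell of the row forced by the row margin
            v = row_left[i]
            if 0 <= v <= col_left[c - 1]:
                table[i, c - 1] = v
                col_left[c - 1] -= v
                yield from fill(i + 1, 0, row_left, col_left)
                col_left[c - 1] += v
            return
        hi = min(row_left[i], col_left[j])
        for v in range(hi + 1):
            table[i, j] = v
            row_left[i] -= v
            col_left[j] -= v
            yield from fill(i, j + 1, row_left, col_left)
            row_left[i] += v
            col_left[j] += v

    yield from fill(0, 0, row_margins.copy(), col_margins.copy())


def fisher_exact(table, max_tables: float = 5e6) -> float:
    """Two-sided exact p-value for an r x c contingency table with fixed margins."""
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValidationError("negative count in contingency table")
    row_margins = table.sum(axis=1)
    col_margins = table.sum(axis=0)
    n = int(table.sum())
    if (row_margins == 0).any() or (col_margins == 0).any() or n == 0:
        return 1.0  # degenerate: a zero margin fixes the table

    free = (table.shape[0] - 1) * (table.shape[1] - 1)
    bound = 1.0
    for i in range(table.shape[0] - 1):
        for j in range(table.shape[1] - 1):
            bound *= min(row_margins[i], col_margins[j]) + 1
            if bound > max_tables:
                raise CapacityError(
                    f"enumeration bound {bound:.3g} tables exceeds budget {max_tables:.3g} "
                    f"for a {table.shape[0]}x{table.shape[1]} table with N={n}"
                )
    _ = free

    log_obs = _log_table_prob(table, row_margins, col_margins, n)
    p_obs = np.exp(log_obs)
    total = 0.0
    for t in _enumerate_tables(row_margins, col_margins):
        p = np.exp(_log_table_prob(t, row_margins, col_margins, n))
        if p <= p_obs * _REL_TOL:
            total += p
    return float(min(total, 1.0))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U statistic of x, p-value).

    Exact permutation null when both samples have n <= 12 and the pooled data
    are tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size <= 12 and y.size <= 12 and no_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AssociationReport:
    """One row per factor: test used, statistic, p-value and per-group summaries."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


_DEFAULT_CATEGORICAL = ["surgery", "smoker", "copd", "histology", "stage"]
_DEFAULT_CONTINUOUS = CONTINUOUS_COVARIATES + ["kps"]


def _summarise_continuous(v: np.ndarray) -> str:
    return f"{np.min(v):g}-{np.max(v):g} ({np.median(v):g})"


def screen_factors(
    phenotypes: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> AssociationReport:
    """Test each clinical factor against the endpoint, one factor at a time."""
    phenotypes = validate_phenotypes(phenotypes)
    continuous = _DEFAULT_CONTINUOUS if continuous is None else continuous
    categorical = _DEFAULT_CATEGORICAL if categorical is None else categorical
    pos = phenotypes[phenotypes["endpoint"] == 1]
    neg = phenotypes[phenotypes["endpoint"] == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both endpoint groups must be non-empty")

    rows = []
    for col in continuous:
        xv, yv = pos[col].to_numpy(dtype=float), neg[col].to_numpy(dtype=float)
        note = ""
        if np.unique(np.concatenate([xv, yv])).size == 1:
            u, p, note = np.nan, 1.0, "constant factor"
        else:
            u, p = mann_whitney_u(xv, yv)
        rows.append((col, "mann-whitney", u, p, _summarise_continuous(xv), _summarise_continuous(yv), note))
    for col in categorical:
        levels = sorted(phenotypes[col].unique())
        note = ""
        if len(levels) < 2:
            rows.append((col, "fisher", np.nan, 1.0, "", "", "constant factor"))
            continue
        counts = np.array(
            [[int((g[col] == lev).sum()) for g in (pos, neg)] for lev in levels]
        )
        p = fisher_exact(counts)
        summ = lambda g: "; ".join(
            f"{lev}: {int((g[col] == lev).sum())} ({100 * (g[col] == lev).mean():.1f}%)" for lev in levels
        )
        rows.append((col, "fisher", np.nan, p, summ(pos), summ(neg), note))

    return AssociationReport(
        pd.DataFrame(
            rows,
            columns=["factor", "test", "statistic", "p_value", "endpoint_pos", "endpoint_neg", "note"],
        )
    )
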