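"""Fisher exact and Mann-Whitney screening of clinical factors."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rpindex.clinical import CapacityError, fisher_exact, mann_whitney_u, screen_factors
from rpindex.datatypes import ValidationError
from rpindex.simulate import SyntheticSpec, simulate_cohort


def fisher_oracle(table) -> float:
    """Exact-rational enumeration over all tables with the observed margins."""
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    if (rows == 0).any() or (cols == 0).any():
        return 1.0

    from math import factorial

    def prob(t):
        # multivariate hypergeometric: prod(r_i!) prod(c_j!) / (n! prod t_ij!)
        num = 1
        for r in rows:
            num *= factorial(int(r))
        for c in cols:
            num *= factorial(int(c))
        den = factorial(int(n))
        for x in t.ravel():
            den *= factorial(int(x))
        return Fraction(num, den)

    def gen(row_idx, remaining_cols, current):
        if row_idx == len(rows) - 1:
            last = remaining_cols
            if (last >= 0).all():
                yield np.vstack(current + [last])
            return
        for combo in itertools.product(
            *[range(min(int(rows[row_idx]), int(c)) + 1) for c in remaining_cols[:-1]]
        ):
            last = int(rows[row_idx]) - sum(combo)
            if last < 0 or last > remaining_cols[-1]:
                continue
            row = np.array(combo + (last,))
            yield from gen(row_idx + 1, remaining_cols - row, current + [row])

    p_obs = prob(table)
    total = Fraction(0)
    for t in gen(0, cols.copy(), []):
        p = prob(t)
        if p <= p_obs:
            total += p
    return float(total)


def test_modal_table_gives_p_one():
    assert fisher_exact([[5, 5], [5, 5]]) == 1.0


def test_zero_margin_degenerates_to_one():
    assert fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_fisher_invariant_under_row_and_column_permutation():
    t = np.array([[9, 41], [1, 67]])
    p = fisher_exact(t)
    assert fisher_exact(t[::-1]) == pytest.approx(p, rel=1e-12)
    assert fisher_exact(t[:, ::-1]) == pytest.approx(p, rel=1e-12)
    assert fisher_exact(t.T) == pytest.approx(p, rel=1e-12)


def test_fisher_2x2_equals_enumeration_oracle_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(40):
        t = rng.integers(0, 8, size=(2, 2))
        assert fisher_exact(t) == pytest.approx(fisher_oracle(t), rel=1e-9), t


def test_fisher_rxc_equals_enumeration_oracle():
    rng = np.random.default_rng(6)
    for shape in [(3, 2), (2, 3), (3, 3)]:
        for _ in range(10):
            t = rng.integers(0, 5, size=shape)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(fisher_oracle(t), rel=1e-9), t


def test_fisher_capacity_guard_is_explicit():
    big = np.full((4, 4), 500)
    with pytest.raises(CapacityError, match="budget"):
        fisher_exact(big, max_tables=1000)


def test_fisher_rejects_negative_and_tiny_tables():
    with pytest.raises(ValidationError):
        fisher_exact([[1, -1], [2, 3]])
    with pytest.raises(ValidationError):
        fisher_exact([[1, 2]])


def mw_permutation_oracle(x, y):
    """Two-sided exact p by enumerating all assignments of pooled ranks."""
    pooled = np.concatenate([x, y])
    n_x = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    n = len(pooled)
    mean_u = n_x * (n - n_x) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - n_x * (n_x + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


def test_mann_whitney_fully_separated_small_samples():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 of the 20 rank assignments are as extreme


def test_mann_whitney_identical_samples_is_uninformative():
    _, p = mann_whitney_u([3, 1, 2, 2], [2, 1, 3, 2])
    assert p >= 0.99


def test_mann_whitney_exact_path_matches_permutation_oracle():
    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.permutation(100)[: rng.integers(3, 7)].astype(float)
        y = rng.permutation(200)[100:][: rng.integers(3, 7)].astype(float)
        if len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
            continue
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mw_permutation_oracle(x, y), rel=1e-9)


def test_mann_whitney_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(9)
    x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
    _, p1 = mann_whitney_u(x, y)
    _, p2 = mann_whitney_u(np.exp(x), np.exp(y))
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_mann_whitney_rejects_empty_sample():
    with pytest.raises(ValidationError):
        mann_whitney_u([], [1.0])


def test_screen_factors_routes_tests_and_flags_constants():
    spec = SyntheticSpec(n_samples=150, n_snps=10, n_causal=0, causal_coefficients=(),
                         intercept=0.0, seed=4)
    _, phen, _ = simulate_cohort(spec)
    phen = phen.copy()
    phen["kps"] = 80  # constant factor
    report = screen_factors(phen).to_frame()
    assert set(report["factor"]) >= {"age", "mld", "surgery", "histology", "kps"}
    by = report.set_index("factor")
    assert by.loc["age", "test"] == "mann-whitney"
    assert by.loc["surgery", "test"] == "fisher"
    assert by.loc["kps", "p_value"] == 1.0
    assert "constant" in by.loc["kps", "note"]
    assert (report["p_value"] > 0).all() and (report["p_value"] <= 1).all()

    # categorical routing agrees with a directly built contingency table
    pos, neg = phen[phen.endpoint == 1], phen[phen.endpoint == 0]
    t = [[int((g["copd"] == lev).sum()) for g in (pos, neg)] for lev in (0, 1)]
    assert by.loc["copd", "p_value"] == pytest.approx(fisher_exact(t))
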