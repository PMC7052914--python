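"""Site-level quality control: summary statistics, the exact HWE test, filtering."""

import math
from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest

from rpindex.datatypes import ValidationError, VariantRecord
from rpindex.genotype_io import encode_cohort
from rpindex.qc import QCThresholds, apply_qc, compute_maf, compute_missingness, hwe_exact_test
from rpindex.simulate import SyntheticSpec, simulate_cohort

NAN = float("nan")


def hwe_enumeration_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_homref + n_het + n_homalt
    na = 2 * n_homref + n_het        # count of the first allele
    weights = {}
    for het in range(min(na, 2 * n - na) + 1):
        homref2 = na - het
        if homref2 % 2:
            continue
        a, c = homref2 // 2, (2 * n - na - het) // 2
        if a < 0 or c < 0 or a + het + c != n:
            continue
        weights[het] = Fraction(factorial(n) * 2 ** het,
                                factorial(a) * factorial(het) * factorial(c))
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


@pytest.mark.parametrize(
    "col,expected",
    [([0, 1, 2, NAN], 0.25), ([0, 1, 2], 0.0), ([NAN] * 4, 1.0)],
)
def test_missingness_counts_nan_fraction(col, expected):
    assert compute_missingness(np.array(col)) == expected


@pytest.mark.parametrize(
    "col,expected",
    [
        ([0, 1, 2], 0.5),            # 3 alt alleles out of 6
        ([0, 0, 0], 0.0),
        ([2, 2, 2, 1], 1 / 8),       # min(7/8, 1/8): minor allele is REF
        ([0, 1, 2, NAN], 0.5),       # missing excluded from the denominator
    ],
)
def test_maf_allele_counting(col, expected):
    assert compute_maf(np.array(col)) == pytest.approx(expected)


def test_maf_undefined_on_all_missing():
    with pytest.raises(ValidationError, match="missing"):
        compute_maf(np.array([NAN, NAN]))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(10, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


def test_hwe_two_minor_alleles_full_enumeration():
    # 2 minor alleles in 2 diploids: het count 0 or 2 with weights 1 and 2
    assert hwe_exact_test(0, 2, 0) == pytest.approx(hwe_enumeration_oracle(0, 2, 0))
    assert hwe_exact_test(1, 0, 1) == pytest.approx(hwe_enumeration_oracle(1, 0, 1))


def test_hwe_equals_enumeration_oracle_small_sweep():
    # exhaustive over all genotype-count triples with total <= 12
    for total in range(1, 13):
        for a in range(total + 1):
            for b in range(total - a + 1):
                c = total - a - b
                assert hwe_exact_test(a, b, c) == pytest.approx(
                    hwe_enumeration_oracle(a, b, c), rel=1e-10
                ), (a, b, c)


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValidationError):
        hwe_exact_test(-1, 2, 3)


def _toy_cohort(columns, gencall=None):
    """Cohort from explicit dosage columns (dict site_id -> list of 0/1/2/nan)."""
    from rpindex.datatypes import GenotypeCohort

    site_ids = list(columns)
    n = len(next(iter(columns.values())))
    variants = [
        VariantRecord(s, "1", 10 + j, "A", ("G",),
                      None if gencall is None else gencall[j])
        for j, s in enumerate(site_ids)
    ]
    calls = np.empty((n, len(site_ids), 2), dtype="U8")
    for j, s in enumerate(site_ids):
        for i, d in enumerate(columns[s]):
            if isinstance(d, float) and math.isnan(d):
                calls[i, j] = ("", "")
            else:
                calls[i, j] = [("A", "A"), ("A", "G"), ("G", "G")][int(d)]
    return GenotypeCohort([f"S{i}" for i in range(n)], variants, calls)


def test_low_maf_site_excluded_with_reason():
    # 1 alt allele in 200 -> MAF 0.005 < 0.01; the balanced site passes
    rare = [1] + [0] * 99
    common = [0, 1, 2, 1] * 25
    cohort = _toy_cohort({"rare": rare, "common": common})
    filtered, encoded, report = apply_qc(cohort)
    assert report.excluded_ids() == ["rare"]
    row = report.per_site.set_index("site_id").loc["rare"]
    assert row["failures"] == "maf"
    assert encoded.site_ids == ["common"]


def test_all_passing_sites_returned_unchanged():
    common = [0, 1, 2, 1] * 25
    cohort = _toy_cohort({"a": common, "b": common[::-1]})
    filtered, encoded, report = apply_qc(cohort)
    assert filtered.equals(cohort)
    assert report.sites_out == report.sites_in == 2


def test_failure_reasons_recorded_per_filter():
    all_het = [1] * 100                          # extreme heterozygote excess
    low_gc = [0, 1, 2, 1] * 25
    cohort = _toy_cohort({"bad": all_het, "dim": low_gc}, gencall=[0.95, 0.5])
    _, _, report = apply_qc(cohort)
    failures = dict(zip(report.per_site["site_id"], report.per_site["failures"]))
    assert failures["bad"] == "hwe"
    assert failures["dim"] == "gencall"


def test_missingness_filter_uses_unfiltered_column():
    col = [0, 1, NAN, NAN, 1, 2, 0, 1, 2, 1]     # 20% missing > 5%
    cohort = _toy_cohort({"holey": col, "ok": [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]})
    _, _, report = apply_qc(cohort)
    assert report.excluded_ids() == ["holey"]


def test_apply_qc_is_idempotent(noisy_cohort):
    _, cohort, _, _ = noisy_cohort
    filtered, encoded, report = apply_qc(cohort)
    filtered2, encoded2, report2 = apply_qc(filtered)
    assert report2.sites_out == report2.sites_in == report.sites_out
    assert filtered2.equals(filtered)
    np.testing.assert_array_equal(encoded.values, encoded2.values)


def test_planted_hwe_violating_sites_are_excluded():
    spec = SyntheticSpec(
        n_samples=2000, n_snps=120, n_causal=0, causal_coefficients=(),
        intercept=0.0, missing_rate=0.0, fraction_multiallelic=0.0,
        fraction_offref=0.0, n_hwe_violating=5, seed=21,
        maf_distribution=("uniform", 0.1, 0.5),
    )
    cohort, _, _ = simulate_cohort(spec)
    _, _, report = apply_qc(cohort)
    per = report.per_site.set_index("site_id")
    # the generator marks no ids, so detect the planted sites by their
    # excess-het signature: p-values far below any sampling fluctuation
    planted = per[per["hwe_p"] < 1e-8]
    assert len(planted) == 5
    assert (planted["failures"].str.contains("hwe")).all()
    # all planted sites excluded, at alpha 1e-6
    assert set(planted.index) <= set(report.excluded_ids())


def test_multiallelic_exclusion_before_encoding(noisy_cohort):
    _, cohort, _, _ = noisy_cohort
    _, encoded, report = apply_qc(cohort)
    multi = {v.site_id for v in cohort.variants if v.is_multiallelic}
    assert multi
    assert multi.isdisjoint(encoded.site_ids)
    assert report.totals["multiallelic"] == len(multi)


def test_thresholds_validated():
    with pytest.raises(ValidationError):
        QCThresholds(max_missingness=1.0)
    with pytest.raises(ValidationError):
        QCThresholds(hwe_alpha=0.0)
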