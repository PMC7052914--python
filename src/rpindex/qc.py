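"""Per-site SNP quality control.

Four exclusion filters plus multi-allelic exclusion, applied per site on the
unfiltered cohort (so filter order cannot matter):

* mean GenCall score < 0.7 (array call confidence; skipped with a warning when
  no scores are available),
* call missingness > 5%,
* minor allele frequency < 1%,
* Hardy-Weinberg equilibrium exact test p < 1e-6.

MAF and the HWE test are computed on non-missing calls only.  The HWE test is
the exact conditional test: given the allele counts, the two-sided p-value sums
the probabilities of all heterozygote counts whose conditional probability does
not exceed that of the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import EncodedMatrix, GenotypeCohort, ValidationError
from .genotype_io import encode_cohort

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCReport", "compute_missingness", "compute_maf", "hwe_exact_test", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    min_mean_gencall: float = 0.7
    max_missingness: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    exclude_multiallelic: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_mean_gencall <= 1.0):
            raise ValidationError("min_mean_gencall outside [0,1]")
        if not (0.0 <= self.max_missingness < 1.0):
            raise ValidationError("max_missingness outside [0,1)")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValidationError("min_maf outside [0,0.5]")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValidationError("hwe_alpha outside (0,1)")


@dataclass
class QCReport:
    """Per-site statistics, verdicts and failing filters, plus per-filter totals."""

    per_site: pd.DataFrame
    sites_in: int
    sites_out: int
    totals: dict[str, int] = field(default_factory=dict)

    def excluded_ids(self) -> list[str]:
        return self.per_site.loc[~self.per_site["pass"], "site_id"].tolist()


def compute_missingness(column: np.ndarray) -> float:
    """Fraction of missing (NaN) entries in one encoded-dosage column."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValidationError("empty column")
    return float(np.isnan(column).mean())


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency from dosages: min(f, 1-f) with f = sum/(2 n_nonmissing)."""
    column = np.asarray(column, dtype=float)
    ok = ~np.isnan(column)
    if not ok.any():
        raise ValidationError("MAF undefined: all calls missing")
    f = column[ok].sum() / (2.0 * ok.sum())
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the allele counts: over all heterozygote counts of the
    correct parity, sums the conditional probabilities not exceeding that of
    the observed count.  Monomorphic sites give p = 1.
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het), ("n_homalt", n_homalt)):
        if v < 0 or v != int(v):
            raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValidationError("at least one genotype required")
    n_minor = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if n_minor == 0:
        return 1.0
    # log P(het = h | allele counts) up to a shared constant:
    #   n! / (homref! het! homalt!) * 2^het  with fixed allele counts
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    rare_hom = (n_minor - hets) // 2
    common_hom = n - hets - rare_hom
    valid = common_hom >= 0
    hets, rare_hom, common_hom = hets[valid], rare_hom[valid], common_hom[valid]
    logp = hets * np.log(2.0) - gammaln(rare_hom + 1) - gammaln(hets + 1) - gammaln(common_hom + 1)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValidationError(
            f"impossible genotype configuration ({n_homref},{n_het},{n_homalt})"
        )
    # 1+1e-12 guards against float noise when several configs tie with the mode
    p = probs[probs <= obs[0] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_from_column(column: np.ndarray) -> float:
    ok = ~np.isnan(column)
    vals = column[ok]
    return hwe_exact_test(int((vals == 0).sum()), int((vals == 1).sum()), int((vals == 2).sum()))


def apply_qc(
    cohort: GenotypeCohort,
    encoded: EncodedMatrix | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeCohort, EncodedMatrix, QCReport]:
    """Apply all enabled per-site filters; returns the filtered cohort, its encoding and a report.

    Multi-allelic sites are excluded before encoding (the dosage encoding
    presumes a single designated ALT), so ``encoded`` may be omitted and is
    recomputed for the biallelic sites.  A site is removed iff it fails at
    least one enabled filter, each computed on the unfiltered column.
    """
    if encoded is not None and encoded.site_ids != cohort.site_ids:
        raise ValidationError("encoded matrix not aligned with cohort sites")

    multi = np.array([v.is_multiallelic for v in cohort.variants], dtype=bool)
    biallelic_idx = np.flatnonzero(~multi)
    bi_encoded = encode_cohort(cohort.subset_sites(biallelic_idx))

    n_sites = cohort.n_sites
    miss = np.full(n_sites, np.nan)
    maf = np.full(n_sites, np.nan)
    hwe = np.full(n_sites, np.nan)
    for k, j in enumerate(biallelic_idx):
        col = bi_encoded.values[:, k]
        miss[j] = compute_missingness(col)
        if np.isnan(col).all():
            maf[j] = np.nan  # undefined; the missingness filter removes such sites
            hwe[j] = np.nan
        else:
            maf[j] = compute_maf(col)
            hwe[j] = _hwe_from_column(col)
    gencall = np.array(
        [np.nan if v.mean_gencall is None else v.mean_gencall for v in cohort.variants]
    )

    have_gencall = not np.isnan(gencall[~multi]).all() if (~multi).any() else False
    if not have_gencall and (~multi).any():
        logger.warning("mean GenCall scores absent; GenCall filter skipped")

    failures: list[list[str]] = [[] for _ in range(n_sites)]
    for j in range(n_sites):
        if multi[j]:
            if thresholds.exclude_multiallelic:
                failures[j].append("multiallelic")
            continue
        if have_gencall and not np.isnan(gencall[j]) and gencall[j] < thresholds.min_mean_gencall:
            failures[j].append("gencall")
        if miss[j] > thresholds.max_missingness:
            failures[j].append("missingness")
        if not np.isnan(maf[j]) and maf[j] < thresholds.min_maf:
            failures[j].append("maf")
        if not np.isnan(hwe[j]) and hwe[j] < thresholds.hwe_alpha:
            failures[j].append("hwe")

    passed = np.array([not f for f in failures], dtype=bool)
    report = QCReport(
        per_site=pd.DataFrame(
            {
                "site_id": cohort.site_ids,
                "missingness": miss,
                "maf": maf,
                "hwe_p": hwe,
                "mean_gencall": gencall,
                "pass": passed,
                "failures": [",".join(f) for f in failures],
            }
        ),
        sites_in=n_sites,
        sites_out=int(passed.sum()),
        totals={
            name: sum(name in f for f in failures)
            for name in ("multiallelic", "gencall", "missingness", "maf", "hwe")
        },
    )
    keep = np.flatnonzero(passed)
    filtered = cohort.subset_sites(keep)
    keep_in_bi = [int(np.searchsorted(biallelic_idx, j)) for j in keep]
    return filtered, bi_encoded.subset_sites(keep_in_bi), report
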