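"""Core containers for genotype cohorts, encoded dosage matrices and model coefficients.

Conventions used throughout the package:

* Genotype calls are stored as pairs of literal allele strings (``("A", "G")``);
  a missing call is the empty pair ``("", "")``.
* Encoded dosage matrices are ``float64`` arrays with entries in ``{0, 1, 2}``
  and ``NaN`` marking a missing call.
* Coordinates are 1-based, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeCohort",
    "EncodedMatrix",
    "CoefficientTable",
    "PHENOTYPE_COLUMNS",
    "CONTINUOUS_COVARIATES",
    "validate_phenotypes",
]

_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """An input violated a structural invariant; the message names the field."""


@dataclass(frozen=True)
class VariantRecord:
    """A genotyped site: identifier, locus, reference allele and designated ALT allele(s).

    ``alt_alleles`` lists the designated alternative alleles: exactly one for a
    biallelic site, two or more for a multi-allelic site.  Calls in a cohort may
    carry alleles outside REF/ALT ("off-reference" array calls); those do not
    make the site multi-allelic.
    """

    site_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    mean_gencall: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position} at {self.site_id}")
        if not self.ref_allele or not _BASES.issuperset(self.ref_allele):
            raise ValidationError(f"ref_allele must be an uppercase A/C/G/T string at {self.site_id}")
        for a in self.alt_alleles:
            if not a or not _BASES.issuperset(a):
                raise ValidationError(f"alt allele {a!r} invalid at {self.site_id}")
        if self.ref_allele in self.alt_alleles:
            raise ValidationError(f"ref allele appears in alt_alleles at {self.site_id}")
        if self.mean_gencall is not None and not (0.0 <= self.mean_gencall <= 1.0):
            raise ValidationError(f"mean_gencall outside [0,1] at {self.site_id}")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alt_alleles) > 1

    @property
    def alt_allele(self) -> str:
        """The single designated ALT of a biallelic site."""
        if self.is_multiallelic:
            raise ValidationError(f"site {self.site_id} is multi-allelic")
        return self.alt_alleles[0]


@dataclass
class GenotypeCohort:
    """Samples x sites diploid genotype calls plus per-site metadata.

    ``calls`` has shape ``(n_samples, n_sites, 2)`` and dtype ``<U`` (allele
    strings); both entries of a missing call are ``""``.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        ids = [v.site_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate site ids: {dup[:5]}")
        expected = (len(self.sample_ids), len(self.variants), 2)
        if self.calls.shape != expected:
            raise ValidationError(f"calls shape {self.calls.shape} != {expected}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def site_ids(self) -> list[str]:
        return [v.site_id for v in self.variants]

    def subset_sites(self, keep: Sequence[int]) -> "GenotypeCohort":
        keep = list(keep)
        return GenotypeCohort(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in keep],
            calls=self.calls[:, keep, :].copy(),
        )

    def equals(self, other: "GenotypeCohort") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and bool(np.array_equal(self.calls, other.calls))
        )


@dataclass
class EncodedMatrix:
    """Samples x sites dosage matrix: entries 0/1/2, ``NaN`` = missing call."""

    sample_ids: list[str]
    site_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} != ({len(self.sample_ids)}, {len(self.site_ids)})"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("encoded values must be 0, 1, 2 or NaN")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset_sites(self, keep: Sequence[int]) -> "EncodedMatrix":
        keep = list(keep)
        return EncodedMatrix(
            sample_ids=list(self.sample_ids),
            site_ids=[self.site_ids[i] for i in keep],
            values=self.values[:, keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.site_ids)


@dataclass
class CoefficientTable:
    """The portable artifact of a fit: selected sites, their log-odds weights, and the intercept.

    ``entries`` columns: site_id, chromosome, position, ref_allele, alt_allele,
    coefficient.  ``alpha``/``lambda_`` record the elastic-net hyperparameters;
    ``threshold`` is the RPI classification cut-off (default 0.5).
    """

    entries: pd.DataFrame
    intercept: float
    alpha: float = 0.5
    lambda_: float = 0.0
    threshold: float = 0.5

    _COLUMNS = ["site_id", "chromosome", "position", "ref_allele", "alt_allele", "coefficient"]

    def __post_init__(self) -> None:
        self.entries = pd.DataFrame(self.entries, columns=self._COLUMNS).reset_index(drop=True)
        if self.entries["site_id"].duplicated().any():
            dup = self.entries.loc[self.entries["site_id"].duplicated(), "site_id"].tolist()
            raise ValidationError(f"duplicate site ids in coefficient table: {dup[:5]}")
        if not np.isfinite(self.entries["coefficient"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite coefficient")
        if not np.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha outside [0,1]: {self.alpha}")
        if self.lambda_ < 0:
            raise ValidationError(f"negative lambda: {self.lambda_}")

    @property
    def site_ids(self) -> list[str]:
        return self.entries["site_id"].tolist()

    @property
    def coefficients(self) -> np.ndarray:
        return self.entries["coefficient"].to_numpy(dtype=float)

    def equals(self, other: "CoefficientTable") -> bool:
        return (
            self.entries.equals(other.entries)
            and self.intercept == other.intercept
            and self.alpha == other.alpha
            and self.lambda_ == other.lambda_
            and self.threshold == other.threshold
        )


# Phenotype/covariate table schema (one row per sample, indexed by sample_id).
PHENOTYPE_COLUMNS = [
    "rp_grade",
    "endpoint",
    "age",
    "total_dose",
    "fractional_dose",
    "v5",
    "v10",
    "v20",
    "v30",
    "mld",
    "surgery",
    "smoker",
    "copd",
    "histology",
    "stage",
    "kps",
]

CONTINUOUS_COVARIATES = ["age", "total_dose", "fractional_dose", "v5", "v10", "v20", "v30", "mld"]


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: endpoint = (rp_grade >= 2), ranges sane.

    The grade >=2 endpoint is the study's primary outcome (CTCAE grade 2 means
    symptoms requiring medical intervention).
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    grades = df["rp_grade"].to_numpy()
    if not np.isin(grades, range(6)).all():
        raise ValidationError("rp_grade must be an integer in 0..5")
    if not (df["endpoint"].to_numpy() == (grades >= 2).astype(int)).all():
        raise ValidationError("endpoint must equal (rp_grade >= 2)")
    for col in ("v5", "v10", "v20", "v30"):
        v = df[col].to_numpy(dtype=float)
        if ((v < 0) | (v > 100)).any():
            raise ValidationError(f"{col} outside [0,100]")
    for col in ("total_dose", "fractional_dose", "mld", "age"):
        if (df[col].to_numpy(dtype=float) < 0).any():
            raise ValidationError(f"negative {col}")
    for col in ("surgery", "smoker", "copd"):
        if not np.isin(df[col].to_numpy(), (0, 1)).all():
            raise ValidationError(f"{col} must be binary 0/1")
    return df
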