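"""Synthetic genotype cohorts with the structure the pneumonitis analysis assumes.

The generator emulates a radiotherapy cohort genotyped on a SNP array: biallelic
sites in Hardy-Weinberg proportions with a drawn MAF spectrum, a sparse causal
architecture acting additively on the 0/1/2 ALT dosage through a logistic
outcome model, clinical covariates drawn independently of outcome (the study
setting: dosimetric and phenotypic factors carry little signal), and array
artefacts — missing calls, per-site mean GenCall scores, multi-allelic sites,
off-reference allele calls, and optionally heterozygote-excess sites that
violate Hardy-Weinberg equilibrium (so the QC filter has true positives).

Sites are simulated independently: no linkage-disequilibrium blocks and no
population stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeCohort,
    ValidationError,
    VariantRecord,
    validate_phenotypes,
)
from . import genotype_io

__all__ = ["SyntheticSpec", "TruthRecord", "simulate_cohort", "write_fixture", "read_truth"]

_BASES = np.array(["A", "C", "G", "T"])

# Covariate distributions defaulted to the study cohort's published summary
# statistics (medians/ranges of age, doses, lung volumes, comorbidity rates).
DEFAULT_COVARIATES: dict[str, tuple] = {
    "age": ("normal", 60.0, 9.0, 36.0, 79.0),
    "total_dose": ("normal", 61.6, 7.0, 30.0, 70.0),
    "fractional_dose": ("normal", 2.4, 0.4, 2.0, 7.0),
    "v5": ("normal", 51.0, 14.0, 13.8, 86.0),
    "v10": ("normal", 34.2, 10.0, 4.0, 60.0),
    "v20": ("normal", 20.0, 6.0, 2.0, 30.5),
    "v30": ("normal", 12.0, 4.5, 2.0, 23.1),
    "mld": ("normal", 11.6, 3.5, 3.3, 19.0),
    "surgery": ("bernoulli", 0.085),
    "smoker": ("bernoulli", 0.822),
    "copd": ("bernoulli", 0.339),
    "histology": ("choice", ["squamous", "adeno", "small_cell", "other"],
                  [41 / 118, 19 / 118, 53 / 118, 5 / 118]),
    "stage": ("choice", ["I-II", "III", "IV"], [7 / 118, 86 / 118, 25 / 118]),
    "kps": ("choice", [70, 80, 90], [0.1, 0.3, 0.6]),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated cohort; identical spec + seed gives a bit-identical cohort.

    Defaults mirror the emulated study: 118 patients, ~42% grade >=2
    pneumonitis prevalence (``intercept`` = logit 0.42 with the symmetric
    default effects), a uniform MAF spectrum on [0.01, 0.5] and a sparse
    five-site causal architecture on the log-odds scale of the encoded dosage.
    ``n_snps`` defaults to a desk-scale 5000 sites; the array scale (~700k) is
    reachable by setting it explicitly.
    """

    n_samples: int = 118
    n_snps: int = 5000
    maf_distribution: tuple = ("uniform", 0.01, 0.5)
    n_causal: int = 5
    causal_coefficients: tuple[float, ...] = (1.8, 1.6, 1.5, -1.6, -1.8)
    intercept: float = -0.32
    covariate_spec: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    missing_rate: float = 0.01
    gencall_mean_distribution: tuple = ("beta", 40.0, 2.5)
    fraction_multiallelic: float = 0.005
    fraction_offref: float = 0.002
    n_hwe_violating: int = 0
    hwe_het_prob: float = 0.95
    target_prevalence: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValidationError("n_causal must satisfy 0 <= n_causal <= n_snps")
        if len(self.causal_coefficients) != self.n_causal:
            raise ValidationError(
                f"causal_coefficients has length {len(self.causal_coefficients)}, "
                f"expected n_causal={self.n_causal}"
            )
        for name in ("missing_rate", "fraction_multiallelic", "fraction_offref"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must lie in [0,1), got {v}")
        if self.n_hwe_violating < 0 or self.n_hwe_violating > self.n_snps:
            raise ValidationError("n_hwe_violating outside [0, n_snps]")
        if not (0.0 < self.hwe_het_prob <= 1.0):
            raise ValidationError("hwe_het_prob outside (0,1]")
        if not np.isfinite(self.intercept):
            raise ValidationError("intercept must be finite")
        if self.target_prevalence is not None and not (0.0 < self.target_prevalence < 1.0):
            raise ValidationError("target_prevalence outside (0,1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort: the causal model and per-sample risk."""

    causal_site_ids: list[str]
    causal_coefficients: np.ndarray
    intercept: float
    probabilities: np.ndarray        # per-sample sigmoid(linear predictor)
    causal_dosages: np.ndarray       # samples x causal sites, pre-noise 0/1/2
    mafs: np.ndarray                 # drawn per-site ALT allele frequencies


def _draw(dist: tuple, size, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size)
    if kind == "normal":
        _, mu, sd, lo, hi = dist
        return np.clip(rng.normal(mu, sd, size), lo, hi)
    if kind == "bernoulli":
        return (rng.random(size) < dist[1]).astype(int)
    if kind == "choice":
        return rng.choice(np.asarray(dist[1]), size=size, p=dist[2])
    raise ValidationError(f"unknown distribution {kind!r}")


def _simulate_phenotypes(spec: SyntheticSpec, y: np.ndarray, rng: np.random.Generator,
                         sample_ids: list[str]) -> pd.DataFrame:
    n = len(y)
    # CTCAE grade consistent with the binary endpoint: cases mostly grade 2-3
    grades = np.where(
        y == 1,
        rng.choice([2, 3, 4, 5], size=n, p=[0.75, 0.20, 0.04, 0.01]),
        rng.choice([0, 1], size=n, p=[0.6, 0.4]),
    )
    cols: dict[str, np.ndarray] = {"rp_grade": grades, "endpoint": (grades >= 2).astype(int)}
    for name, dist in spec.covariate_spec.items():
        cols[name] = _draw(dist, n, rng)
    df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return validate_phenotypes(df)


def simulate_cohort(spec: SyntheticSpec) -> tuple[GenotypeCohort, pd.DataFrame, TruthRecord]:
    """Simulate a genotype cohort, its phenotype table and the generating truth.

    Genotypes are Hardy-Weinberg binomial(2, MAF) dosages; the outcome is
    Bernoulli(sigmoid(intercept + sum of causal coefficient x dosage)).  Causal
    sites are drawn among clean biallelic sites (never the injected
    multi-allelic or HWE-violating ones).  Off-reference calls and missingness
    are injected after the outcome is drawn, so they act purely as encoding
    noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_snps

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    width = len(str(m))
    site_ids = [f"SNP{j + 1:0{width}d}" for j in range(m)]
    chroms = np.sort(rng.integers(1, 23, size=m)).astype(str)
    positions = rng.integers(1, 250_000_000, size=m)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    refs, alts = _BASES[ref_idx], _BASES[alt_idx]

    mafs = _draw(spec.maf_distribution, m, rng)
    mafs = np.clip(mafs, 1e-6, 0.5)
    dosage = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)

    # heterozygote-excess sites exercising the HWE filter
    special = rng.choice(m, size=spec.n_hwe_violating, replace=False) if spec.n_hwe_violating else np.array([], dtype=int)
    for j in special:
        het = rng.random(n) < spec.hwe_het_prob
        hom = rng.random(n) < mafs[j]
        dosage[:, j] = np.where(het, 1, np.where(hom, 2, 0))

    n_multi = int(round(spec.fraction_multiallelic * m))
    eligible = np.setdiff1d(np.arange(m), special)
    multi = rng.choice(eligible, size=n_multi, replace=False) if n_multi else np.array([], dtype=int)

    clean = np.setdiff1d(eligible, multi)
    if spec.n_causal > len(clean):
        raise ValidationError("not enough clean biallelic sites for the causal set")
    causal = np.sort(rng.choice(clean, size=spec.n_causal, replace=False))
    coefs = np.asarray(spec.causal_coefficients, dtype=float)

    intercept = spec.intercept
    if spec.target_prevalence is not None:
        # calibrate baseline risk to the drawn MAFs so the mean linear
        # predictor sits at logit(target_prevalence)
        t = spec.target_prevalence
        intercept = float(np.log(t / (1 - t)) - (2.0 * mafs[causal]) @ coefs)
    eta = intercept + dosage[:, causal].astype(float) @ coefs
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < prob).astype(int)
    truth = TruthRecord(
        causal_site_ids=[site_ids[j] for j in causal],
        causal_coefficients=coefs.copy(),
        intercept=intercept,
        probabilities=prob,
        causal_dosages=dosage[:, causal].astype(float).copy(),
        mafs=mafs.copy(),
    )

    # materialise allele-pair calls from dosages
    calls = np.empty((n, m, 2), dtype="U8")
    calls[:, :, 0] = np.where(dosage == 2, alts, refs)
    calls[:, :, 1] = np.where(dosage >= 1, alts, refs)

    alt2_idx = np.full(m, -1)
    for j in multi:
        choices = [b for b in range(4) if b not in (ref_idx[j], alt_idx[j])]
        alt2_idx[j] = rng.choice(choices)
        replace = rng.random(n) < 0.15  # second ALT segregates at low frequency
        which = rng.integers(0, 2, size=n)
        for s in np.flatnonzero(replace):
            calls[s, j, which[s]] = _BASES[alt2_idx[j]]

    if spec.fraction_offref > 0:
        mask = rng.random((n, m)) < spec.fraction_offref
        mask[:, multi] = False
        which = rng.integers(0, 2, size=(n, m))
        for s, j in zip(*np.nonzero(mask)):
            others = [b for b in "ACGT" if b not in (refs[j], alts[j])]
            calls[s, j, which[s, j]] = others[rng.integers(0, len(others))]

    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        calls[miss] = ""

    gencall = np.clip(_draw(spec.gencall_mean_distribution, m, rng), 0.0, 1.0)

    variants = []
    for j in range(m):
        alt_list = (alts[j],) if alt2_idx[j] < 0 else (alts[j], str(_BASES[alt2_idx[j]]))
        variants.append(
            VariantRecord(
                site_id=site_ids[j],
                chromosome=chroms[j],
                position=int(positions[j]),
                ref_allele=str(refs[j]),
                alt_alleles=alt_list,
                mean_gencall=float(gencall[j]),
            )
        )
    cohort = GenotypeCohort(sample_ids, variants, calls)
    phenotypes = _simulate_phenotypes(spec, y, rng, sample_ids)
    return cohort, phenotypes, truth


def write_fixture(
    cohort: GenotypeCohort,
    phenotypes: pd.DataFrame,
    truth: TruthRecord | None,
    out_dir: str | Path,
    format: str = "vcf",
) -> dict[str, Path]:
    """Write a simulated cohort to disk: genotypes, phenotype table, truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if list(phenotypes.index) != cohort.sample_ids:
        raise ValidationError("phenotype rows do not match cohort sample ids")
    geno = out / ("genotypes.vcf" if format == "vcf" else "genotypes.tsv")
    genotype_io.write_genotypes(cohort, geno, format=format)
    pheno = out / "phenotypes.tsv"
    genotype_io.write_phenotypes(phenotypes, pheno)
    paths = {"genotypes": geno, "phenotypes": pheno}
    if truth is not None:
        tpath = out / "truth.tsv"
        with open(tpath, "w") as fh:
            fh.write(f"#intercept={float(truth.intercept)!r}\n")
            fh.write("site_id\tcoefficient\n")
            for sid, c in zip(truth.causal_site_ids, truth.causal_coefficients):
                fh.write(f"{sid}\t{float(c)!r}\n")
        paths["truth"] = tpath
    return paths


def read_truth(path: str | Path) -> tuple[list[str], np.ndarray, float]:
    """Read a truth sidecar back: (site_ids, coefficients, intercept)."""
    intercept = 0.0
    sids: list[str] = []
    coefs: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#intercept="):
                intercept = float(line.split("=", 1)[1])
            elif line.startswith("site_id"):
                continue
            elif line.strip():
                sid, c = line.split("\t")
                sids.append(sid)
                coefs.append(float(c))
    return sids, np.array(coefs), intercept
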