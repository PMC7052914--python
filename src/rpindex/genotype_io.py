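"""Readers/writers for genotype, phenotype and coefficient files, and the 0/1/2 dosage encoding.

The dosage encoding is reference-relative: each allele of a diploid call is
compared, as a literal string, with the site's REF ("wild type" on GRCh37) and
its designated ALT.  An allele equal to ALT scores 1; an allele equal to REF
scores 0; an allele matching neither ("off-reference") also scores 0.  The site
value is the sum of the two allelic values, an integer in 0..2; a missing call
propagates as missing.  No strand flipping or allele harmonisation is applied.

Two on-disk genotype dialects are supported:

* VCF 4.x (GT field only).  Off-reference alleles observed in calls are
  appended to the ALT column after the designated ALT(s); the ``NDALT`` INFO
  key records how many leading ALTs are designated, so biallelic sites with
  off-reference noise calls round-trip without becoming multi-allelic.
  ``GCM`` carries the per-site mean GenCall score.
* A tabular allele-pair dialect: samples as rows, sites as columns, entries
  like ``A/G`` (``./.`` missing), with a ``<path>.sites.tsv`` metadata sidecar.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    PHENOTYPE_COLUMNS,
    CoefficientTable,
    EncodedMatrix,
    GenotypeCohort,
    ValidationError,
    VariantRecord,
    validate_phenotypes,
)

MISSING_CALL = ("", "")

__all__ = [
    "encode_site",
    "encode_cohort",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_coefficients",
    "write_coefficients",
]


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_allele(allele: str, variant: VariantRecord) -> int:
    """Score one allele against a biallelic site: ALT -> 1, REF or other -> 0."""
    return 1 if allele == variant.alt_allele else 0


def encode_site(call: tuple[str, str], variant: VariantRecord) -> float:
    """Encode one diploid call as the 0/1/2 ALT-allele dosage (NaN if missing).

    Total on valid inputs: off-reference alleles contribute 0 per allele, so
    e.g. (ALT, off-ref) -> 1 and (off-ref, off-ref) -> 0.
    """
    if call[0] == "" or call[1] == "":
        return math.nan
    return float(encode_allele(call[0], variant) + encode_allele(call[1], variant))


def encode_cohort(cohort: GenotypeCohort) -> EncodedMatrix:
    """Encode every call of a cohort; requires all sites biallelic (run QC first)."""
    multi = [v.site_id for v in cohort.variants if v.is_multiallelic]
    if multi:
        raise ValidationError(
            f"multi-allelic sites present (e.g. {multi[:3]}); apply QC with "
            "multi-allelic exclusion before encoding"
        )
    alts = np.array([v.alt_alleles[0] for v in cohort.variants])
    values = (cohort.calls[:, :, 0] == alts).astype(float) + (cohort.calls[:, :, 1] == alts)
    values[cohort.calls[:, :, 0] == ""] = np.nan
    return EncodedMatrix(list(cohort.sample_ids), cohort.site_ids, values)


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

def write_genotypes_vcf(cohort: GenotypeCohort, path: str | Path) -> None:
    """Write a cohort as VCF 4.2 with GT calls.

    Alleles observed in calls but absent from REF and the designated ALT(s)
    are appended to the ALT column (VCF requires every called allele listed);
    NDALT marks how many leading ALTs are designated.
    """
    path = Path(path)
    contigs = []
    seen_contig: set[str] = set()
    for v in cohort.variants:
        if v.chromosome not in seen_contig:
            seen_contig.add(v.chromosome)
            contigs.append(f"##contig=<ID={v.chromosome}>")
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=NDALT,Number=1,Type=Integer,Description="Number of designated ALT alleles">',
        '##INFO=<ID=GCM,Number=1,Type=String,Description="Mean GenCall score (full precision)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *contigs,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.sample_ids),
    ]
    for j, var in enumerate(cohort.variants):
        observed = cohort.calls[:, j, :]
        extra = sorted(
            {a for a in observed.ravel() if a and a != var.ref_allele and a not in var.alt_alleles}
        )
        alts = list(var.alt_alleles) + extra
        index = {var.ref_allele: 0}
        index.update({a: i + 1 for i, a in enumerate(alts)})
        gts = []
        for s in range(cohort.n_samples):
            a0, a1 = observed[s]
            gts.append("./." if a0 == "" else f"{index[a0]}/{index[a1]}")
        info = f"NDALT={len(var.alt_alleles)}"
        if var.mean_gencall is not None:
            info += f";GCM={var.mean_gencall!r}"
        lines.append(
            f"{var.chromosome}\t{var.position}\t{var.site_id}\t{var.ref_allele}\t"
            f"{','.join(alts)}\t.\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path: str | Path) -> GenotypeCohort:
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for rec in vcf:
        site_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if site_id in seen:
            raise ValidationError(f"duplicate site_id {site_id!r} in {path}")
        seen.add(site_id)
        alts = list(rec.ALT)
        ndalt = rec.INFO.get("NDALT")
        n_designated = int(ndalt) if ndalt is not None else len(alts)
        gcm = rec.INFO.get("GCM")
        variants.append(
            VariantRecord(
                site_id=site_id,
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_alleles=tuple(alts[:n_designated]),
                mean_gencall=float(gcm) if gcm is not None else None,
            )
        )
        alleles = [rec.REF] + alts
        col = np.empty((len(sample_ids), 2), dtype="U8")
        for s, g in enumerate(rec.genotypes):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col[s] = MISSING_CALL
            else:
                col[s, 0], col[s, 1] = alleles[a0], alleles[a1]
        columns.append(col)
    vcf.close()
    if columns:
        calls = np.stack(columns, axis=1)
    else:
        calls = np.empty((len(sample_ids), 0, 2), dtype="U8")
    return GenotypeCohort(sample_ids, variants, calls)


# ---------------------------------------------------------------------------
# Tabular allele-pair dialect
# ---------------------------------------------------------------------------

def _sites_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".sites.tsv")


def write_genotypes_table(cohort: GenotypeCohort, path: str | Path) -> None:
    """Write calls as sample-rows x site-columns ``A/G`` entries plus a site sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(cohort.site_ids) + "\n")
        for s, sid in enumerate(cohort.sample_ids):
            cells = [
                "./." if a0 == "" else f"{a0}/{a1}" for a0, a1 in cohort.calls[s]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
    with open(_sites_sidecar(path), "w") as fh:
        fh.write("site_id\tchromosome\tposition\tref_allele\talt_alleles\tmean_gencall\n")
        for v in cohort.variants:
            gc = "" if v.mean_gencall is None else repr(v.mean_gencall)
            fh.write(
                f"{v.site_id}\t{v.chromosome}\t{v.position}\t{v.ref_allele}\t"
                f"{','.join(v.alt_alleles)}\t{gc}\n"
            )


def read_genotypes_table(path: str | Path) -> GenotypeCohort:
    path = Path(path)
    sites = pd.read_csv(_sites_sidecar(path), sep="\t", dtype=str, keep_default_na=False)
    variants = [
        VariantRecord(
            site_id=row.site_id,
            chromosome=row.chromosome,
            position=int(row.position),
            ref_allele=row.ref_allele,
            alt_alleles=tuple(row.alt_alleles.split(",")),
            mean_gencall=float(row.mean_gencall) if row.mean_gencall else None,
        )
        for row in sites.itertuples()
    ]
    table = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if list(table.columns) != [v.site_id for v in variants]:
        raise ValidationError(f"site columns of {path} disagree with sites sidecar")
    calls = np.empty((table.shape[0], table.shape[1], 2), dtype="U8")
    for i, (_, row) in enumerate(table.iterrows()):
        for j, cell in enumerate(row):
            if cell in (".", "./."):
                calls[i, j] = MISSING_CALL
            else:
                try:
                    a0, a1 = cell.replace("|", "/").split("/")
                except ValueError:
                    raise ValidationError(f"malformed call {cell!r} at row {i + 2} of {path}")
                calls[i, j, 0], calls[i, j, 1] = a0, a1
    return GenotypeCohort(list(table.index), variants, calls)


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeCohort:
    """Read a genotype cohort; ``format`` is ``"vcf"`` or ``"table"``."""
    if format == "vcf":
        return read_genotypes_vcf(path)
    if format == "table":
        return read_genotypes_table(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def write_genotypes(cohort: GenotypeCohort, path: str | Path, format: str = "vcf") -> None:
    if format == "vcf":
        write_genotypes_vcf(cohort, path)
    elif format == "table":
        write_genotypes_table(cohort, path)
    else:
        raise ValidationError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Phenotype and coefficient tables
# ---------------------------------------------------------------------------

def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_phenotypes(df)


def write_coefficients(table: CoefficientTable, path: str | Path) -> None:
    """Serialise a coefficient table as TSV with a commented hyperparameter header.

    Floats are written with ``repr`` so the round trip is exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#intercept={table.intercept!r}\n")
        fh.write(f"#alpha={table.alpha!r}\n")
        fh.write(f"#lambda={table.lambda_!r}\n")
        fh.write(f"#threshold={table.threshold!r}\n")
        fh.write("site_id\tchromosome\tposition\tref_allele\talt_allele\tcoefficient\n")
        for row in table.entries.itertuples():
            fh.write(
                f"{row.site_id}\t{row.chromosome}\t{row.position}\t{row.ref_allele}\t"
                f"{row.alt_allele}\t{row.coefficient!r}\n"
            )


def read_coefficients(path: str | Path) -> CoefficientTable:
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, value = line[1:].strip().partition("=")
        try:
            meta[key] = float(value)
        except ValueError:
            raise ValidationError(f"non-numeric header value {value!r} for {key!r} in {path}")
    header = lines[body_start].rstrip("\n").split("\t")
    expected = ["site_id", "chromosome", "position", "ref_allele", "alt_allele", "coefficient"]
    if header != expected:
        raise ValidationError(f"coefficient table header {header} != {expected}")
    rows = []
    for k, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            raise ValidationError(f"malformed coefficient row at line {k} of {path}")
        try:
            rows.append(parts[:2] + [int(parts[2])] + parts[3:5] + [float(parts[5])])
        except ValueError:
            raise ValidationError(f"non-numeric field at line {k} of {path}")
    entries = pd.DataFrame(rows, columns=expected)
    return CoefficientTable(
        entries=entries,
        intercept=meta.get("intercept", 0.0),
        alpha=meta.get("alpha", 0.5),
        lambda_=meta.get("lambda", 0.0),
        threshold=meta.get("threshold", 0.5),
    )
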