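"""Reading, additive coding and filtering of cohort phenotype/genotype data.

Phenotypes arrive as a TSV with one row per measurement (longitudinal cohorts
record each individual up to four times); genotypes arrive either as a VCF
(GT field, biallelic diploid sites only) or as a plain dosage TSV.  Genotypes
are coded additively: 0, 1 or 2 copies of the alternate allele, with missing
calls kept as missing until the filter step removes them.

The filter pipeline applies, in order:

(a) keep individuals with at least one measurement with complete hypertension
    and age information (and reduce to the first such measurement);
(b) drop monomorphic variants and variants whose non-majority genotypes are
    carried by fewer than two individuals;
(c) drop individuals with more than 5% missing genotype calls (strictly more);
(d) drop variants that still have a missing call in any retained individual.

The result is a complete (no-missing) analysis-ready dataset.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PhenotypeRecord",
    "VariantRecord",
    "GenotypeMatrix",
    "FilteredDataset",
    "DataError",
    "FormatError",
    "ConfigurationError",
    "read_phenotypes",
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "first_measurement",
    "apply_filters",
]

#: Sentinel for a missing genotype call in the integer dosage matrix.
MISSING: int = -1

DEFAULT_PHENOTYPE_DIALECT: Mapping[str, str] = {
    "individual_id": "individual_id",
    "hypertension": "hypertension",
    "age": "age",
    "gender": "gender",
    "smoking": "smoking",
    "measurement_index": "measurement_index",
}


class DataError(ValueError):
    """Raised when input data violate a structural requirement."""


class FormatError(ValueError):
    """Raised when a file cannot be interpreted in the declared format."""


class ConfigurationError(ValueError):
    """Raised when a dialect/column mapping cannot be resolved."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One phenotype measurement for one individual.

    ``hypertension`` is 0/1 (or None when unrecorded), ``age`` is in years.
    ``measurement_index`` counts longitudinal visits starting at 1.
    """

    individual_id: str
    hypertension: int | None
    age: float | None
    gender: str | None = None
    smoking: str | None = None
    measurement_index: int = 1

    def __post_init__(self) -> None:
        if self.hypertension is not None and self.hypertension not in (0, 1):
            raise DataError(
                f"hypertension must be 0/1 or missing, got {self.hypertension!r} "
                f"for individual {self.individual_id}"
            )
        if self.age is not None and not (0 < self.age < 130):
            raise DataError(
                f"age must lie in (0, 130), got {self.age!r} for individual "
                f"{self.individual_id}"
            )
        if self.measurement_index < 1:
            raise DataError("measurement_index must be >= 1")

    @property
    def complete(self) -> bool:
        """True when both hypertension status and age are recorded."""
        return self.hypertension is not None and self.age is not None


@dataclass(frozen=True)
class VariantRecord:
    """Metadata for one biallelic variant (rsID or chrom:pos naming)."""

    variant_id: str
    chromosome: str = "."
    position: int = 1
    ref_allele: str = "A"
    alt_allele: str = "B"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"position must be >= 1 for {self.variant_id}")
        if not self.ref_allele or not self.alt_allele:
            raise DataError(f"alleles must be non-empty for {self.variant_id}")


@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix.

    ``dosages`` is an int8 array with entries in {0, 1, 2, MISSING}.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise DataError("dosage matrix must be 2-dimensional")
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise DataError("row count does not match number of individual ids")
        if m != len(self.variants):
            raise DataError("column count does not match number of variants")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid][0]
            raise DataError(f"dosage entries must be 0/1/2 or missing, got {bad}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset(
        self,
        individuals: Sequence[int] | None = None,
        variants: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            individual_ids=[self.individual_ids[i] for i in rows],
            variants=[self.variants[j] for j in cols],
        )


@dataclass
class FilteredDataset:
    """Output of the filter pipeline: complete phenotypes + complete genotypes.

    ``filter_log`` lists ``(criterion, item_type, item_id)`` triples, one per
    removed individual or variant, in removal order.
    """

    phenotypes: list[PhenotypeRecord]
    genotypes: GenotypeMatrix
    filter_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotypes.missing_mask().any():
            raise DataError("filtered genotype matrix must not contain missing calls")
        for rec in self.phenotypes:
            if not rec.complete:
                raise DataError(
                    f"filtered phenotype for {rec.individual_id} has missing "
                    "hypertension or age"
                )
        ids = [r.individual_id for r in self.phenotypes]
        if ids != self.genotypes.individual_ids:
            raise DataError("phenotype and genotype individual order differ")

    @property
    def y(self) -> np.ndarray:
        return np.array([r.hypertension for r in self.phenotypes], dtype=float)

    @property
    def age(self) -> np.ndarray:
        return np.array([r.age for r in self.phenotypes], dtype=float)

    def removed_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for criterion, _, _ in self.filter_log:
            counts[criterion] = counts.get(criterion, 0) + 1
        return counts

    def write_filter_log(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            self.filter_log, columns=["criterion", "item_type", "item_id"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip() in ("", "NA", "nan", "."):
            return None
        return float(value)
    return float(value)


def _parse_optional_int(value) -> int | None:
    v = _parse_optional_float(value)
    return None if v is None else int(v)


def _parse_optional_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in ("", "NA", "nan", ".") else s


def read_phenotypes(
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
) -> list[PhenotypeRecord]:
    """Read a phenotype TSV into records, one per measurement row.

    ``dialect`` maps canonical field names (``individual_id``,
    ``hypertension``, ``age``, optionally ``gender``, ``smoking``,
    ``measurement_index``) to the file's column names.  Missing cells stay
    missing; they are never replaced by sentinel numbers.
    """
    dial = dict(DEFAULT_PHENOTYPE_DIALECT)
    if dialect:
        dial.update(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read phenotype file {path}: {exc}") from exc
    for required in ("individual_id", "hypertension", "age"):
        if dial[required] not in df.columns:
            raise ConfigurationError(
                f"required phenotype column {dial[required]!r} (for "
                f"{required!r}) not found in {list(df.columns)}"
            )
    has_meas = dial["measurement_index"] in df.columns
    records: list[PhenotypeRecord] = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                individual_id=str(row[dial["individual_id"]]),
                hypertension=_parse_optional_int(row[dial["hypertension"]]),
                age=_parse_optional_float(row[dial["age"]]),
                gender=_parse_optional_str(row.get(dial["gender"])),
                smoking=_parse_optional_str(row.get(dial["smoking"])),
                measurement_index=(
                    _parse_optional_int(row[dial["measurement_index"]]) or 1
                    if has_meas
                    else 1
                ),
            )
        )
    seen: set[tuple[str, int]] = set()
    for rec in records:
        key = (rec.individual_id, rec.measurement_index)
        if key in seen:
            raise DataError(
                f"duplicated (individual, measurement) pair {key} in {path}"
            )
        seen.add(key)
    return records


_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def _read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise FormatError(
                f"multi-allelic site {record.CHROM}:{record.POS} not supported"
            )
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(record.genotypes):
            alleles = tuple(gt[:-1])  # last element is the phasing flag
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid call for sample {sample_ids[i]} at "
                    f"{record.CHROM}:{record.POS}"
                )
            if -1 in alleles:
                col[i] = MISSING
            else:
                try:
                    col[i] = _GT_CODE[alleles]
                except KeyError:
                    raise FormatError(
                        f"unsupported genotype {alleles} at {record.CHROM}:{record.POS}"
                    ) from None
        columns.append(col)
        variants.append(
            VariantRecord(
                variant_id=record.ID or f"{record.CHROM}:{record.POS}",
                chromosome=record.CHROM,
                position=record.POS,
                ref_allele=record.REF,
                alt_allele=record.ALT[0],
            )
        )
    dosages = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(dosages, sample_ids, variants)


def _read_dosage_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    dosages = np.full(values.shape, MISSING, dtype=np.int8)
    present = ~np.isnan(values)
    rounded = np.round(values[present])
    if not np.isin(rounded, (0, 1, 2)).all() or np.abs(values[present] - rounded).max(
        initial=0.0
    ) > 0:
        bad = values[present][~np.isin(rounded, (0, 1, 2)) | (values[present] != rounded)]
        raise FormatError(
            f"dosage TSV {path} contains non-{{0,1,2}} entries, e.g. {bad[:3]}"
        )
    dosages[present] = rounded.astype(np.int8)
    variants = [VariantRecord(variant_id=str(c)) for c in df.columns]
    return GenotypeMatrix(dosages, [str(i) for i in df.index], variants)


def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes as additive dosages from a VCF or a dosage TSV.

    VCF GT coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multi-allelic and non-diploid records are rejected with a
    :class:`FormatError` naming the site.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write an uncompressed VCFv4.2 file carrying only the GT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen: list[str] = []
        for var in genotypes.variants:
            if var.chromosome not in seen:
                seen.append(var.chromosome)
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for j, var in enumerate(genotypes.variants):
            calls = "\t".join(_DOSAGE_GT[int(d)] for d in genotypes.dosages[:, j])
            fh.write(
                f"{var.chromosome}\t{var.position}\t{var.variant_id}\t"
                f"{var.ref_allele}\t{var.alt_allele}\t.\t.\t.\tGT\t{calls}\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        np.where(genotypes.dosages == MISSING, np.nan, genotypes.dosages),
        index=genotypes.individual_ids,
        columns=[v.variant_id for v in genotypes.variants],
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# filtering


def first_measurement(
    records: Iterable[PhenotypeRecord],
) -> tuple[list[PhenotypeRecord], list[str]]:
    """Reduce longitudinal records to the first complete measurement.

    For each individual, keep the record with the smallest measurement index
    among those with non-missing hypertension *and* age ("first available").
    Individuals with no complete measurement are dropped; their ids are
    returned for logging.
    """
    by_id: dict[str, list[PhenotypeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.individual_id not in by_id:
            order.append(rec.individual_id)
        by_id.setdefault(rec.individual_id, []).append(rec)
    kept: list[PhenotypeRecord] = []
    dropped: list[str] = []
    for iid in order:
        complete = [r for r in by_id[iid] if r.complete]
        if complete:
            kept.append(min(complete, key=lambda r: r.measurement_index))
        else:
            dropped.append(iid)
    return kept, dropped


def _polymorphic_ok(column: np.ndarray) -> bool:
    """Criterion (b): non-majority genotypes carried by >= 2 individuals."""
    observed = column[column != MISSING]
    if observed.size == 0:
        return False
    counts = np.bincount(observed, minlength=3)
    return counts.sum() - counts.max() >= 2


def apply_filters(
    phenotypes: Sequence[PhenotypeRecord],
    genotypes: GenotypeMatrix,
    missing_rate_threshold: float = 0.05,
) -> FilteredDataset:
    """Apply the four filter criteria (a)-(d), in that order.

    (a) complete-phenotype reduction, (b) polymorphism filter, (c) individual
    genotype-missingness filter at the strict ``missing_rate_threshold``
    (individuals with missing fraction strictly greater are excluded),
    (d) removal of variants with any remaining missing call.
    """
    log: list[tuple[str, str, str]] = []

    kept, dropped = first_measurement(phenotypes)
    pheno_ids = {r.individual_id for r in kept}
    geno_ids = set(genotypes.individual_ids)
    for iid in dropped:
        if iid in geno_ids:
            log.append(("a", "individual", iid))
    shared = [iid for iid in genotypes.individual_ids if iid in pheno_ids]
    if not shared:
        raise DataError("no individuals shared between phenotypes and genotypes")
    # individuals genotyped but lacking any complete phenotype measurement
    for iid in genotypes.individual_ids:
        if iid not in pheno_ids and iid not in dropped:
            log.append(("a", "individual", iid))
    rec_by_id = {r.individual_id: r for r in kept}
    idx = [genotypes.individual_ids.index(iid) for iid in shared]
    G = genotypes.subset(individuals=idx)

    # (b) on individuals surviving (a)
    keep_cols = [j for j in range(G.n_variants) if _polymorphic_ok(G.dosages[:, j])]
    for j in range(G.n_variants):
        if j not in set(keep_cols):
            log.append(("b", "variant", G.variants[j].variant_id))
    G = G.subset(variants=keep_cols)
    if G.n_variants == 0:
        raise DataError("all variants removed by polymorphism filter (b)")

    # (c) strict "> threshold" exclusion
    miss_frac = G.missing_mask().mean(axis=1)
    keep_rows = [i for i in range(G.n_individuals) if miss_frac[i] <= missing_rate_threshold]
    for i in range(G.n_individuals):
        if miss_frac[i] > missing_rate_threshold:
            log.append(("c", "individual", G.individual_ids[i]))
    G = G.subset(individuals=keep_rows)
    if G.n_individuals == 0:
        raise DataError("all individuals removed by missingness filter (c)")

    # (d) variants with any remaining missing call
    still_missing = G.missing_mask().any(axis=0)
    for j in np.flatnonzero(still_missing):
        log.append(("d", "variant", G.variants[j].variant_id))
    G = G.subset(variants=list(np.flatnonzero(~still_missing)))
    if G.n_variants == 0:
        raise DataError("all variants removed by missing-call filter (d)")

    # re-check (b) on the final individuals: dropping rows in (c) can turn a
    # variant monomorphic; without this pass the output invariant (and
    # idempotence of the whole filter) would not hold
    keep_cols = [j for j in range(G.n_variants) if _polymorphic_ok(G.dosages[:, j])]
    for j in range(G.n_variants):
        if j not in set(keep_cols):
            log.append(("b", "variant", G.variants[j].variant_id))
    G = G.subset(variants=keep_cols)
    if G.n_variants == 0:
        raise DataError("all variants removed by polymorphism filter (b)")

    phenos = [rec_by_id[iid] for iid in G.individual_ids]
    return FilteredDataset(phenotypes=phenos, genotypes=G, filter_log=log)
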