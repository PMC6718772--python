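"""Genotype and read-depth matrices, averages, and metadata grouping.

Filtered records are turned into two variants × samples grids:

* a categorical genotype matrix with four display classes — homozygous
  reference (0), heterozygous (1), homozygous variant (2), no call (3) —
  derived from the GT FORMAT field;
* a numeric read-depth matrix from the DP FORMAT field, with "." kept as a
  missing mark (NaN), never imputed as zero coverage.

Sample metadata is a CSV of binary traits (rows) × samples (columns) with
values in {1, 2} and "--" for missing.  Grouping by one trait stably
reorders matrix columns (group 1, then group 2, then missing) so that
case/control contrasts or facility batch effects line up side by side in
the heatmaps.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .errors import (EmptyResultError, InputError, MalformedDepthError,
                     MalformedGenotypeError, MalformedMetadataError,
                     MissingFieldError, OutputError)
from .vcf_stream import MISSING, VariantRecord, VCFHeader

logger = logging.getLogger(__name__)

#: Missing sentinel used in metadata CSVs and tabular exports.
MISSING_SENTINEL = "--"


class GenotypeCategory(IntEnum):
    """The four display classes; codes are stable (they key the color scale)."""

    HOM_REF = 0
    HET = 1
    HOM_VAR = 2
    NO_CALL = 3

    @property
    def display_name(self) -> str:
        return _CATEGORY_NAMES[self]


_CATEGORY_NAMES = {
    GenotypeCategory.HOM_REF: "homozygous reference",
    GenotypeCategory.HET: "heterozygous variant",
    GenotypeCategory.HOM_VAR: "homozygous variant",
    GenotypeCategory.NO_CALL: "no call",
}


def encode_genotype(gt: str) -> GenotypeCategory:
    """Classify a raw GT string into one of the four display classes.

    "/" and "|" separators are both accepted (phasing is ignored); any
    missing allele makes the call NO_CALL; all-reference is HOM_REF;
    all-equal non-reference is HOM_VAR; anything mixed with at least one
    non-reference allele (e.g. "0/1", "1/2") is HET.  Haploid and
    higher-ploidy values follow the same all/equal logic.
    """
    alleles = gt.replace("|", "/").split("/")
    if not alleles or alleles == [""]:
        raise MalformedGenotypeError(f"empty GT value {gt!r}")
    for a in alleles:
        if a == MISSING:
            return GenotypeCategory.NO_CALL
        if not a.isdigit():
            raise MalformedGenotypeError(f"malformed GT value {gt!r}: allele {a!r}")
    if all(a == "0" for a in alleles):
        return GenotypeCategory.HOM_REF
    if len(set(alleles)) == 1:
        return GenotypeCategory.HOM_VAR
    return GenotypeCategory.HET


@dataclass
class GenotypeMatrix:
    """Variants × samples grid of category codes (int8)."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # int8, shape (n_variants, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("genotype grid shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class DepthMatrix:
    """Variants × samples grid of read depths; NaN marks missing."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # float64, shape (n_variants, n_samples), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("depth grid shape does not match labels")
        if np.nanmin(self.values, initial=0) < 0:
            raise MalformedDepthError("negative read depth in matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class SampleMetadata:
    """Binary traits per sample: values in {1, 2}, 0 encodes missing."""

    trait_names: list[str]
    sample_ids: list[str]
    values: np.ndarray  # int8, shape (n_traits, n_samples); 0 = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.trait_names), len(self.sample_ids)):
            raise ValueError("metadata grid shape does not match labels")

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.trait_names:
            raise InputError(
                f"unknown trait {trait!r}; available traits: {self.trait_names}")
        return self.values[self.trait_names.index(trait)]


def _require_records(records: list[VariantRecord]) -> None:
    if not records:
        raise EmptyResultError("no variant records to extract values from")


def extract_genotype_matrix(header: VCFHeader,
                            records: list[VariantRecord]) -> GenotypeMatrix:
    """Encode each record × sample GT into the categorical grid."""
    _require_records(records)
    n = len(records)
    grid = np.empty((n, header.n_samples), dtype=np.int8)
    for i, rec in enumerate(records):
        if "GT" not in rec.format_keys:
            raise MissingFieldError(
                f"record {rec.label} has no GT field in FORMAT {rec.format_keys}")
        for j, sid in enumerate(header.sample_ids):
            grid[i, j] = encode_genotype(rec.calls[sid].get("GT", MISSING))
    return GenotypeMatrix([r.label for r in records], list(header.sample_ids), grid)


def extract_depth_matrix(header: VCFHeader,
                         records: list[VariantRecord]) -> DepthMatrix:
    """Collect per-sample DP values; "." or absent subfields become NaN."""
    _require_records(records)
    n = len(records)
    grid = np.full((n, header.n_samples), np.nan)
    for i, rec in enumerate(records):
        if "DP" not in rec.format_keys:
            raise MissingFieldError(
                f"record {rec.label} has no DP field in FORMAT {rec.format_keys}")
        for j, sid in enumerate(header.sample_ids):
            raw = rec.calls[sid].get("DP", MISSING)
            if raw == MISSING or raw == "":
                continue
            try:
                dp = int(raw)
            except ValueError:
                raise MalformedDepthError(
                    f"record {rec.label}, sample {sid}: non-integer DP {raw!r}") from None
            if dp < 0:
                raise MalformedDepthError(
                    f"record {rec.label}, sample {sid}: negative DP {dp}")
            grid[i, j] = dp
    return DepthMatrix([r.label for r in records], list(header.sample_ids), grid)


def _nanmean(values: np.ndarray, axis: int) -> np.ndarray:
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice -> NaN
        return np.nanmean(values, axis=axis)


def avg_sample_depth(m: DepthMatrix) -> list[tuple[str, float]]:
    """Per-sample mean depth over non-missing entries (NaN if all missing)."""
    return list(zip(m.col_labels, _nanmean(m.values, 0).tolist()))


def avg_variant_depth(m: DepthMatrix) -> list[tuple[str, float]]:
    """Per-variant mean depth over non-missing entries (NaN if all missing)."""
    return list(zip(m.row_labels, _nanmean(m.values, 1).tolist()))


def read_metadata(path: str | os.PathLike,
                  vcf_sample_ids: list[str] | None = None) -> SampleMetadata:
    """Read the trait CSV (header: sample IDs; rows: trait then values).

    Values must be 1, 2 or the "--" missing sentinel.  When *vcf_sample_ids*
    is given, columns are realigned to that order: CSV samples absent from
    the VCF are dropped with a warning, VCF samples absent from the CSV get
    all-missing trait values with a warning.
    """
    if not os.path.exists(path):
        raise InputError(f"metadata file not found: {path}")
    df = pd.read_csv(path, header=0, index_col=0, dtype=str,
                     skipinitialspace=True)
    if df.empty or df.shape[0] < 1:
        raise MalformedMetadataError(f"metadata file {path} defines no traits")
    trait_names = [str(t) for t in df.index]
    csv_samples = [str(c) for c in df.columns]

    def parse_cell(v: object, trait: str, sample: str) -> int:
        s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
        if s in ("", MISSING_SENTINEL, "NA", "nan"):
            return 0
        if s in ("1", "2"):
            return int(s)
        raise MalformedMetadataError(
            f"{path}: trait {trait!r}, sample {sample!r}: value {s!r} "
            "not in {1, 2, '--'}")

    grid = np.zeros((len(trait_names), len(csv_samples)), dtype=np.int8)
    for i, t in enumerate(trait_names):
        for j, s in enumerate(csv_samples):
            grid[i, j] = parse_cell(df.iat[i, j], t, s)

    if vcf_sample_ids is None:
        return SampleMetadata(trait_names, csv_samples, grid)

    extra = [s for s in csv_samples if s not in vcf_sample_ids]
    if extra:
        logger.warning("metadata samples not in VCF header, ignored: %s", extra)
    missing = [s for s in vcf_sample_ids if s not in csv_samples]
    if missing:
        logger.warning("VCF samples absent from metadata, traits set missing: %s",
                       missing)
    aligned = np.zeros((len(trait_names), len(vcf_sample_ids)), dtype=np.int8)
    for j, sid in enumerate(vcf_sample_ids):
        if sid in csv_samples:
            aligned[:, j] = grid[:, csv_samples.index(sid)]
    return SampleMetadata(trait_names, list(vcf_sample_ids), aligned)


def group_by_trait(matrix: GenotypeMatrix | DepthMatrix, meta: SampleMetadata,
                   trait: str) -> tuple[GenotypeMatrix | DepthMatrix, SampleMetadata]:
    """Stably reorder columns by one trait: group 1, then 2, then missing.

    A pure column permutation — values move with their sample labels, the
    metadata is permuted identically, and within each group the original
    order is preserved.
    """
    if matrix.col_labels != meta.sample_ids:
        meta = _align_meta(meta, matrix.col_labels)
    tvals = meta.trait_values(trait)
    # missing (0) sorts last; 1 before 2; stable within groups
    order = np.argsort(np.where(tvals == 0, 3, tvals), kind="stable")
    new_cols = [matrix.col_labels[k] for k in order]
    new_vals = matrix.values[:, order]
    new_meta = SampleMetadata(list(meta.trait_names), new_cols,
                              meta.values[:, order])
    out: GenotypeMatrix | DepthMatrix
    if isinstance(matrix, GenotypeMatrix):
        out = GenotypeMatrix(list(matrix.row_labels), new_cols, new_vals)
    else:
        out = DepthMatrix(list(matrix.row_labels), new_cols, new_vals)
    return out, new_meta


def _align_meta(meta: SampleMetadata, sample_ids: list[str]) -> SampleMetadata:
    aligned = np.zeros((len(meta.trait_names), len(sample_ids)), dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        if sid in meta.sample_ids:
            aligned[:, j] = meta.values[:, meta.sample_ids.index(sid)]
    return SampleMetadata(list(meta.trait_names), list(sample_ids), aligned)


def export_tabular(matrix: GenotypeMatrix | DepthMatrix,
                   meta: SampleMetadata | None,
                   path: str | os.PathLike) -> None:
    """Write the matrix as CSV: header of sample IDs, one row per variant.

    Genotype cells carry category names, depth cells integers; missing cells
    the "--" sentinel.  When metadata is supplied its trait rows are
    prepended above the variant rows (in the current, possibly grouped,
    column order).
    """
    is_geno = isinstance(matrix, GenotypeMatrix)
    try:
        with open(path, "w", encoding="utf-8") as out:
            out.write(",".join([""] + matrix.col_labels) + "\n")
            if meta is not None:
                meta = _align_meta(meta, matrix.col_labels)
                for i, t in enumerate(meta.trait_names):
                    cells = [str(v) if v else MISSING_SENTINEL
                             for v in meta.values[i]]
                    out.write(",".join([t] + cells) + "\n")
            for i, label in enumerate(matrix.row_labels):
                if is_geno:
                    cells = [GenotypeCategory(v).name for v in matrix.values[i]]
                else:
                    cells = [MISSING_SENTINEL if np.isnan(v) else str(int(v))
                             for v in matrix.values[i]]
                out.write(",".join([label] + cells) + "\n")
    except OSError as exc:
        raise OutputError(f"cannot write tabular export to {path}: {exc}") from exc
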