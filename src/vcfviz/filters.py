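"""Streaming variant filters: PASS, position list, genomic range, samples.

Three record-level criteria can be combined (conjunction): keep only records
whose FILTER column is exactly PASS, records at positions named in a
chromosome/position list, and records inside one of a set of genomic ranges
(union across ranges, both endpoints inclusive).  Records are tested as they
stream off the parser and dropped immediately on failure, so memory use is
bounded by the *matching* records only — no index, no preprocessing, no
second pass.

Chromosome names are normalized at comparison time only (case-fold, strip a
leading "chr"), so "1" and "chr1" match across a VCF and a user-supplied CSV
while exported VCFs keep their original names.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import EmptyResultError, InputError, OutputError, UsageError
from .vcf_stream import VariantRecord, VCFHeader, write_vcf

logger = logging.getLogger(__name__)

_RANGE_RE = re.compile(r"^\s*([^:\s]+):(\d+)\s*[-–]\s*(\d+)\s*$")


def normalize_chrom(name: str) -> str:
    """Comparison key for chromosome names: case-folded, 'chr' prefix stripped."""
    low = name.casefold()
    return low[3:] if low.startswith("chr") else low


@dataclass(frozen=True)
class GenomicRange:
    """A chromosome interval; 1-based, both endpoints inclusive."""

    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise UsageError(
                f"invalid range {self.chrom}:{self.start}-{self.stop}: "
                "need 1 <= start <= stop")

    def contains(self, chrom: str, pos: int) -> bool:
        return (normalize_chrom(chrom) == normalize_chrom(self.chrom)
                and self.start <= pos <= self.stop)


@dataclass
class PositionList:
    """Explicit (chromosome, position) pairs to retain; duplicates collapse."""

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise UsageError("position list is empty")
        for chrom, pos in self.entries:
            if pos < 1:
                raise UsageError(f"position list entry {chrom},{pos}: pos must be >= 1")
        self._keys = {(normalize_chrom(c), p) for c, p in self.entries}

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        return (normalize_chrom(chrom), pos) in self._keys


@dataclass
class FilterSpec:
    """Which filters are active.  All absent means keep everything (warned)."""

    pass_only: bool = False
    ranges: list[GenomicRange] = field(default_factory=list)
    positions: PositionList | None = None
    sample_ids: list[str] | None = None

    @property
    def has_record_criteria(self) -> bool:
        return self.pass_only or bool(self.ranges) or self.positions is not None


def parse_genomic_range(text: str) -> GenomicRange:
    """Parse ``<chrom>:<start>-<stop>`` (en dash also accepted) into a range.

    >>> parse_genomic_range("chr1:8900000-12000000")
    GenomicRange(chrom='chr1', start=8900000, stop=12000000)
    """
    m = _RANGE_RE.match(text)
    if not m:
        raise UsageError(
            f"cannot parse genomic range {text!r}; expected <chrom>:<start>-<stop>, "
            "e.g. chr1:8900000-12000000")
    chrom, start, stop = m.group(1), int(m.group(2)), int(m.group(3))
    if start > stop:
        raise UsageError(
            f"genomic range {text!r} has start > stop; expected <chrom>:<start>-<stop>")
    return GenomicRange(chrom, start, stop)


def record_passes(record: VariantRecord) -> bool:
    """True iff FILTER is exactly ["PASS"] (case-sensitive; "." is not a pass)."""
    return record.filter == ["PASS"]


def record_in_ranges(record: VariantRecord, ranges: list[GenomicRange]) -> bool:
    """True iff the record falls inside at least one range (union semantics)."""
    return any(r.contains(record.chrom, record.pos) for r in ranges)


def record_in_position_list(record: VariantRecord, positions: PositionList) -> bool:
    """True iff (normalized chrom, pos) is listed."""
    return (record.chrom, record.pos) in positions


def _matches(record: VariantRecord, spec: FilterSpec) -> bool:
    if spec.pass_only and not record_passes(record):
        return False
    if spec.ranges and not record_in_ranges(record, spec.ranges):
        return False
    if spec.positions is not None and not record_in_position_list(record, spec.positions):
        return False
    return True


def stream_filter(records: Iterable[VariantRecord], spec: FilterSpec,
                  allow_empty: bool = False) -> list[VariantRecord]:
    """Consume the record stream, keeping only records that satisfy *spec*.

    Active criteria combine by conjunction; output preserves file order.
    Non-matching records are released immediately, so peak memory holds the
    matches plus the single record currently under test.

    Raises
    ------
    EmptyResultError
        If nothing matched (unless *allow_empty*); plots of an empty
        selection are meaningless, so the caller is told to relax filters.
    """
    if not spec.has_record_criteria:
        logger.warning(
            "no record-level filter active: every variant will be plotted; "
            "consider --pass, --range or --positions to bound plot size")
    kept: list[VariantRecord] = []
    seen = 0
    for record in records:
        seen += 1
        if _matches(record, spec):
            kept.append(record)
        record = None  # release the non-match before the next line is parsed
    logger.info("filtered %d of %d records", len(kept), seen)
    if not kept and not allow_empty:
        raise EmptyResultError(
            f"no records matched the filter criteria (scanned {seen}); "
            "relax --pass/--range/--positions")
    return kept


def iter_filtered(records: Iterable[VariantRecord],
                  spec: FilterSpec) -> Iterator[VariantRecord]:
    """Lazy variant of :func:`stream_filter` for callers that stream onward."""
    for record in records:
        if _matches(record, spec):
            yield record


def select_samples(header: VCFHeader, records: list[VariantRecord],
                   sample_ids: list[str]) -> tuple[VCFHeader, list[VariantRecord]]:
    """Restrict and reorder per-sample calls to *sample_ids*.

    The returned header and every record's call map follow the requested
    order; values travel with their sample labels.
    """
    unknown = [s for s in sample_ids if s not in header.sample_ids]
    if unknown:
        raise UsageError(
            f"unknown sample IDs {unknown}; available: {header.sample_ids}")
    if not sample_ids:
        raise UsageError("sample selection list is empty")
    new_header = VCFHeader(sample_ids=list(sample_ids),
                           meta_lines=list(header.meta_lines),
                           format_keys_seen=set(header.format_keys_seen))
    new_records = []
    for rec in records:
        calls = {sid: rec.calls[sid] for sid in sample_ids}
        new_records.append(VariantRecord(
            rec.chrom, rec.pos, rec.id, rec.ref, list(rec.alt), rec.qual,
            list(rec.filter), list(rec.format_keys), calls, rec.info))
    return new_header, new_records


def export_filtered_vcf(header: VCFHeader, records: list[VariantRecord],
                        path: str | os.PathLike) -> None:
    """Write the retained records as a valid VCF (original meta lines kept)."""
    try:
        write_vcf(header, records, path)
    except OSError as exc:
        raise OutputError(f"cannot write filtered VCF to {path}: {exc}") from exc


def read_position_list(path: str | os.PathLike) -> PositionList:
    """Read a two-column chromosome,position CSV.

    A single optional header line is skipped when its second field is
    non-numeric (e.g. ``chr,position``).
    """
    if not os.path.exists(path):
        raise InputError(f"position list not found: {path}")
    entries: list[tuple[str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise InputError(
                    f"{path}: line {i + 1}: expected 'chromosome,position', got {line!r}")
            if i == 0 and not parts[1].lstrip("-").isdigit():
                continue  # header line
            try:
                entries.append((parts[0], int(parts[1])))
            except ValueError:
                raise InputError(
                    f"{path}: line {i + 1}: non-integer position {parts[1]!r}") from None
    if not entries:
        raise InputError(f"position list {path} contains no entries")
    return PositionList(entries)


def read_sample_list(path: str | os.PathLike) -> list[str]:
    """Read sample IDs, one per line; an optional single header line
    ('sample', 'sample_id', ...) is skipped."""
    if not os.path.exists(path):
        raise InputError(f"sample list not found: {path}")
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            val = line.strip().split(",")[0].strip()
            if not val:
                continue
            if i == 0 and val.lower() in {"sample", "sample_id", "sampleid", "id"}:
                continue
            ids.append(val)
    if not ids:
        raise InputError(f"sample list {path} contains no sample IDs")
    return ids
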