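"""Index-free streaming VCF reader.

VCF files from whole-exome or whole-genome studies routinely exceed available
memory, and the usual remedy — bgzip + tabix indexing — imposes a
preprocessing step on the user.  This module instead reads the file line by
line (plain text or gzip, detected by magic bytes rather than extension) and
yields one parsed :class:`VariantRecord` at a time, so downstream filtering
can decide record-by-record what to keep.  At no point is more than one
unparsed line plus one record buffered.

Per-sample values are kept as raw strings, positionally paired to the FORMAT
keys; interpretation (genotype classes, integer depths) happens downstream.
Chromosome names are stored verbatim so that a filtered VCF can be exported
byte-faithfully; name normalization is a comparison-time concern of the
filter module.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from dataclasses import dataclass, field
from typing import IO, Iterator

from .errors import InputError, MalformedHeaderError, MalformedRecordError

logger = logging.getLogger(__name__)

#: VCF missing-value sentinel.
MISSING = "."

_FIXED_COLS = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")


@dataclass
class VCFHeader:
    """Parsed VCF header: meta lines, sample order, FORMAT keys seen."""

    sample_ids: list[str]
    meta_lines: list[str] = field(default_factory=list)
    format_keys_seen: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise MalformedHeaderError("VCF header defines no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MalformedHeaderError("duplicate sample IDs in #CHROM line")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


class VariantRecord:
    """One VCF data line.

    ``calls`` maps each sample ID to a dict of FORMAT key -> raw value
    string, in header sample order.  Trailing FORMAT subfields a sample
    omits map to the missing sentinel ".".
    """

    __slots__ = ("chrom", "pos", "id", "ref", "alt", "qual", "filter",
                 "format_keys", "calls", "info", "__weakref__")

    def __init__(self, chrom: str, pos: int, id: str, ref: str,
                 alt: list[str], qual: float | None, filter: list[str],
                 format_keys: list[str], calls: dict[str, dict[str, str]],
                 info: str = MISSING) -> None:
        self.chrom = chrom
        self.pos = pos
        self.id = id
        self.ref = ref
        self.alt = alt
        self.qual = qual
        self.filter = filter
        self.format_keys = format_keys
        self.calls = calls
        self.info = info

    @property
    def label(self) -> str:
        """Row label used throughout: ``<chrom>:<pos>`` verbatim."""
        return f"{self.chrom}:{self.pos}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return all(getattr(self, k) == getattr(other, k)
                   for k in ("chrom", "pos", "id", "ref", "alt", "qual",
                             "filter", "format_keys", "calls", "info"))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"VariantRecord({self.chrom}:{self.pos} {self.ref}->{','.join(self.alt)})"

    def to_line(self, sample_ids: list[str] | None = None) -> str:
        """Serialize back to a tab-delimited VCF data line."""
        if sample_ids is None:
            sample_ids = list(self.calls)
        qual = MISSING if self.qual is None else format_qual(self.qual)
        cols = [self.chrom, str(self.pos), self.id, self.ref,
                ",".join(self.alt) or MISSING, qual,
                ";".join(self.filter), self.info]
        if self.format_keys:
            cols.append(":".join(self.format_keys))
            for sid in sample_ids:
                call = self.calls[sid]
                cols.append(":".join(call.get(k, MISSING) for k in self.format_keys))
        return "\t".join(cols)


def format_qual(q: float) -> str:
    """Render QUAL without a spurious trailing ``.0`` for integral values."""
    return str(int(q)) if float(q).is_integer() else repr(q)


def _open_text(path: str | os.PathLike) -> IO[str]:
    """Open plain or gzip text transparently, sniffing gzip magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8",
                                errors="replace")
    return io.TextIOWrapper(raw, encoding="utf-8", errors="replace")


def parse_record(line: str, header: VCFHeader, line_no: int | None = None) -> VariantRecord:
    """Parse one tab-separated VCF data line against the header sample order.

    FILTER is split on ";" ("." stays a one-element list), ALT on ",", and
    per-sample values are paired positionally to the FORMAT keys; absent
    trailing subfields become ".".
    """
    where = f" (line {line_no})" if line_no is not None else ""
    cols = line.rstrip("\n").rstrip("\r").split("\t")
    if len(cols) < 8:
        raise MalformedRecordError(
            f"data line has {len(cols)} columns, expected at least 8{where}")
    expected = 9 + header.n_samples
    if len(cols) != expected:
        raise MalformedRecordError(
            f"data line has {len(cols)} columns, expected {expected} "
            f"for {header.n_samples} samples{where}")
    chrom, pos_s, rid, ref, alt_s, qual_s, filt_s, info = cols[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise MalformedRecordError(f"non-integer POS {pos_s!r}{where}") from None
    if pos < 1:
        raise MalformedRecordError(f"POS must be >= 1, got {pos}{where}")
    qual = None if qual_s == MISSING else float(qual_s)
    alt = alt_s.split(",") if alt_s != MISSING else [MISSING]
    filt = filt_s.split(";") if filt_s != MISSING else [MISSING]

    format_keys = cols[8].split(":")
    header.format_keys_seen.update(format_keys)
    calls: dict[str, dict[str, str]] = {}
    for sid, raw in zip(header.sample_ids, cols[9:]):
        vals = raw.split(":")
        calls[sid] = {k: (vals[i] if i < len(vals) else MISSING)
                      for i, k in enumerate(format_keys)}
    return VariantRecord(chrom, pos, rid, ref, alt, qual, filt,
                         format_keys, calls, info)


def _records(fh: IO[str], header: VCFHeader, first_line_no: int) -> Iterator[VariantRecord]:
    """Single-pass generator over data lines; never buffers ahead."""
    with fh:
        for line_no, line in enumerate(fh, start=first_line_no):
            if not line.strip():
                continue
            yield parse_record(line, header, line_no)


def open_vcf(path: str | os.PathLike) -> tuple[VCFHeader, Iterator[VariantRecord]]:
    """Open a VCF (plain or gzip) and return its header plus a lazy record stream.

    The returned iterator yields records in file order, one at a time;
    consuming record *k* never requires reading past line *k*.

    Raises
    ------
    InputError
        If the path does not exist.
    MalformedHeaderError
        If no ``#CHROM`` line is found.
    """
    if not os.path.exists(path):
        raise InputError(f"VCF file not found: {path}")
    fh = _open_text(path)
    meta_lines: list[str] = []
    saw_fileformat = False
    line_no = 0
    for line in fh:
        line_no += 1
        line = line.rstrip("\n").rstrip("\r")
        if line.startswith("##"):
            meta_lines.append(line)
            if line.startswith("##fileformat"):
                saw_fileformat = True
        elif line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) < 10 or tuple(cols[:8]) != _FIXED_COLS or cols[8] != "FORMAT":
                # tolerate headers without FORMAT (sites-only) but require samples
                if len(cols) < 10:
                    raise MalformedHeaderError(
                        f"#CHROM line has no sample columns: {line!r}")
            if not saw_fileformat:
                logger.warning("%s: no ##fileformat meta line; proceeding", path)
            header = VCFHeader(sample_ids=cols[9:], meta_lines=meta_lines)
            return header, _records(fh, header, line_no + 1)
        elif line:
            fh.close()
            raise MalformedHeaderError(
                f"unexpected content before #CHROM line at line {line_no}: {line[:80]!r}")
    fh.close()
    raise MalformedHeaderError(f"no #CHROM header line found in {path}")


def write_vcf(header: VCFHeader, records: list[VariantRecord],
              path: str | os.PathLike) -> None:
    """Write a header and records as a plain-text VCF."""
    with open(path, "w", encoding="utf-8") as out:
        for line in header.meta_lines:
            out.write(line + "\n")
        out.write("\t".join(list(_FIXED_COLS) + ["FORMAT"] + header.sample_ids) + "\n")
        for rec in records:
            out.write(rec.to_line(header.sample_ids) + "\n")
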