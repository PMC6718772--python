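"""Exception hierarchy.

Each error class maps to a distinct nonzero exit-status class so that the
command line can translate any failure into a single actionable diagnostic
line.  Library callers catch :class:`VcfVizError`.
"""

from __future__ import annotations


class VcfVizError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(VcfVizError):
    """A required input file is missing or unreadable."""

    exit_code = 3


class UsageError(VcfVizError):
    """Options are malformed or mutually inconsistent."""

    exit_code = 2


class MalformedHeaderError(InputError):
    """The VCF has no #CHROM header line."""


class MalformedRecordError(InputError):
    """A VCF data line cannot be parsed; message cites the line number."""


class MalformedGenotypeError(InputError):
    """A GT value contains a non-numeric, non-missing allele token."""


class MalformedDepthError(InputError):
    """A DP value is negative or not an integer."""


class MalformedMetadataError(InputError):
    """A metadata cell is outside the {1, 2, missing} vocabulary."""


class MissingFieldError(InputError):
    """A required FORMAT key (GT or DP) is absent from a record."""


class EmptyResultError(VcfVizError):
    """Filtering retained zero records; plots would be empty."""

    exit_code = 4


class OutputError(VcfVizError):
    """An artifact could not be written."""

    exit_code = 5
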