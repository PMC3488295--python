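"""Exception hierarchy.

All xenqc errors derive from :class:`XenqcError` so callers can catch the
package's failures with a single except clause; subclasses also derive from
the closest builtin (``ValueError``/``OSError``) for idiomatic handling.
"""


class XenqcError(Exception):
    """Base class for all xenqc errors."""


class FastaFormatError(XenqcError, ValueError):
    """Malformed FASTA input; message carries the offending line number."""


class AlphabetError(XenqcError, ValueError):
    """Sequence character outside the IUPAC nucleotide set; message carries
    record id and 0-based position."""


class SchemaError(XenqcError, ValueError):
    """Tabular input is missing a required column."""


class FlatfileFormatError(XenqcError, ValueError):
    """Malformed GenBank-style flatfile; message carries the record index."""


class InputError(XenqcError, ValueError):
    """Invalid argument value (out-of-range fraction, empty input, ...)."""


class SpecError(XenqcError, ValueError):
    """Contradictory or impossible synthetic-data specification."""
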