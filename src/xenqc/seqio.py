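"""FASTA and TSV input/output.

The rest of the package consumes :class:`SeqRecord` lists and plain
``pandas`` tables produced here; no science happens in this module.

Sequences are uppercased on read, so soft-masking (lowercase) is lost;
downstream analyses never use masking. Characters outside the IUPAC
nucleotide alphabet are rejected with the record id and position rather
than silently converted. Files ending in ``.gz`` are read and written
through transparent gzip.
"""

from __future__ import annotations

import gzip
import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AlphabetError, FastaFormatError, SchemaError

#: IUPAC nucleotide codes (unambiguous + ambiguity letters).
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")


@dataclass
class SeqRecord:
    """A named nucleotide sequence (transcript, contig, scaffold or repeat).

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a file.
    seq : str
        Nucleotide string over the IUPAC alphabet, stored uppercased.
    description : str
        Free-text remainder of the FASTA header line.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = self.seq.upper()
        bad = next((i for i, c in enumerate(self.seq) if c not in IUPAC_NT), None)
        if bad is not None:
            raise AlphabetError(
                f"record {self.id!r}: character {self.seq[bad]!r} at position "
                f"{bad} is not an IUPAC nucleotide code"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path, allow_empty: bool = True) -> list[SeqRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    One record per ``>`` header, input order preserved; sequence lines are
    concatenated with whitespace stripped and uppercased. An empty sequence
    is permitted when *allow_empty* is true but triggers a warning.

    Raises
    ------
    FastaFormatError
        If sequence data precedes the first header (message names the line).
    AlphabetError
        On characters outside the IUPAC nucleotide set.
    """
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        name, _, desc = header.partition(" ")
        seq = "".join(chunks)
        if not seq:
            if not allow_empty:
                raise FastaFormatError(f"record {name!r} has an empty sequence")
            warnings.warn(f"record {name!r} has an empty sequence", stacklevel=3)
        records.append(SeqRecord(id=name, seq=seq, description=desc))

    with _open_text(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append("".join(line.split()))
        flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60) -> None:
    """Write records as wrapped FASTA (``.gz`` suffix gzips transparently)."""
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    with _open_text(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def read_tsv_table(path, required_columns: Sequence[str] = ()) -> list[tuple]:
    """Read a tab-separated table with a header row into named tuples.

    Missing optional cells become ``None``. A required column absent from
    the header raises :class:`SchemaError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    Row = namedtuple("Row", list(df.columns), rename=True)
    out = []
    for row in df.itertuples(index=False):
        out.append(Row(*(None if pd.isna(v) else v for v in row)))
    return out


def write_tsv_table(rows: Iterable[dict], path, columns: Sequence[str]) -> None:
    """Write dict rows as a TSV with the given column order."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)
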