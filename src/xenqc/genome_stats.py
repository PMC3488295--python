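"""Scaffold gap statistics.

A draft genome assembly is distributed as scaffolds in which the unknown
stretches between sequenced sections are written as runs of N. Counting
the contiguous sections and the gap bases gives a simple measure of
assembly fragmentation; the mean section length (assembled bases per
section) is the average distance between gaps, which determines how often
a multi-exon gene locus will be interrupted by a gap.

An N-run must reach ``min_gap_run`` (default 10) to count as a gap;
shorter runs are treated as ordinary ambiguous bases, since real
assemblies contain isolated ambiguity calls that are not gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .errors import InputError
from .seqio import SeqRecord

DEFAULT_MIN_GAP_RUN = 10


@dataclass(frozen=True)
class GapStats:
    """Aggregate section/gap accounting over a set of scaffolds.

    Invariant: ``assembled_bases + gap_bases`` equals the total residue
    count, and ``mean_section_len * n_sections == assembled_bases``.
    """

    n_scaffolds: int
    n_sections: int
    assembled_bases: int
    gap_bases: int

    @property
    def mean_section_len(self) -> float:
        return self.assembled_bases / self.n_sections if self.n_sections else 0.0


def scaffold_sections(seq: str, min_gap_run: int = DEFAULT_MIN_GAP_RUN) -> list[tuple[int, int]]:
    """Maximal non-gap sections of one scaffold, as half-open intervals.

    A gap is an N-run of length >= *min_gap_run*; shorter N-runs stay
    inside their section. An all-gap scaffold has zero sections.
    """
    if not seq:
        raise InputError("empty scaffold")
    if min_gap_run < 1:
        raise InputError("min_gap_run must be positive")
    seq = seq.upper()
    sections = []
    prev_end = 0
    for m in re.finditer("N{%d,}" % min_gap_run, seq):
        if m.start() > prev_end:
            sections.append((prev_end, m.start()))
        prev_end = m.end()
    if prev_end < len(seq):
        sections.append((prev_end, len(seq)))
    return sections


def compute_gap_stats(
    scaffolds: Sequence[SeqRecord], min_gap_run: int = DEFAULT_MIN_GAP_RUN
) -> GapStats:
    """Aggregate gap statistics over an assembly."""
    if not scaffolds:
        raise InputError("no scaffolds given")
    n_sections = 0
    assembled = 0
    total = 0
    for rec in scaffolds:
        total += len(rec.seq)
        secs = scaffold_sections(rec.seq, min_gap_run)
        n_sections += len(secs)
        assembled += sum(e - s for s, e in secs)
    return GapStats(
        n_scaffolds=len(scaffolds),
        n_sections=n_sections,
        assembled_bases=assembled,
        gap_bases=total - assembled,
    )


def mean_intergap_kb(assembled_bases: int, n_sections: int) -> float:
    """Average distance between gaps, i.e. mean section length, in kb to
    one decimal: assembled bases / sections / 1000."""
    if n_sections < 1:
        raise InputError("n_sections must be >= 1")
    return round(assembled_bases / n_sections / 1000, 1)
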