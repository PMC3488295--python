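"""Repeat-coverage screening of transcripts.

Gene models drawn from a repeat-rich genome can be built on transposable
elements or other high-copy sequence rather than on true protein-coding
genes. The screen aligns each transcript against a library of common
repeats, merges the covered transcript intervals, and flags transcripts
whose covered fraction strictly exceeds 80% as probable high-copy-repeat
artifacts.

Identity and length cutoffs for individual hits default to 80% identity
over at least 50 nt; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .align import Scoring, local_align
from .errors import InputError
from .seqio import SeqRecord

#: Fraction of a transcript that must be repeat-covered ("more than 80%").
DEFAULT_REPEAT_THRESHOLD = 0.80


@dataclass(frozen=True)
class RepeatParams:
    """Hit acceptance cutoffs for the repeat scan."""

    min_identity: float = 0.80
    min_hit_len: int = 50
    max_hits_per_entry: int = 64


class RepeatHit(NamedTuple):
    """A local match between a transcript and one repeat-library entry;
    ``q_start``/``q_end`` are on the forward transcript."""

    transcript_id: str
    q_start: int
    q_end: int
    library_id: str
    identity: float


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _entry_hits(
    seq: str, entry: SeqRecord, params: RepeatParams, scoring: Scoring
) -> list[RepeatHit]:
    """All acceptable local hits of one library entry on the transcript.

    The best hit is found, its transcript interval masked, and the scan
    repeated until the residual score cannot support an acceptable hit.
    Masking uses a character outside the nucleotide alphabet so masked
    regions can never re-align.
    """
    # Weakest acceptable hit: min_hit_len columns at exactly min_identity.
    floor = params.min_hit_len * (
        params.min_identity * scoring.match
        + (1 - params.min_identity) * scoring.mismatch
    )
    work = list(seq)
    hits: list[RepeatHit] = []
    for _ in range(params.max_hits_per_entry):
        aln = local_align("".join(work), entry.seq, scoring, both_strands=True)
        if not aln.blocks or aln.score < max(floor, 1):
            break
        q_start, q_end = aln.q_interval_forward()
        if (
            q_end - q_start >= params.min_hit_len
            and aln.identity >= params.min_identity
        ):
            hits.append(
                RepeatHit(
                    transcript_id="",
                    q_start=q_start,
                    q_end=q_end,
                    library_id=entry.id,
                    identity=aln.identity,
                )
            )
        for i in range(q_start, q_end):
            work[i] = "#"
    return hits


def repeat_coverage(
    seq: str,
    repeat_lib: Sequence[SeqRecord],
    params: RepeatParams = RepeatParams(),
    scoring: Scoring = Scoring(),
    transcript_id: str = "",
) -> tuple[float, list[RepeatHit]]:
    """Fraction of a transcript covered by repeat-library matches.

    Local alignments against every library entry (both strands) passing
    the identity/length cutoffs are collected; overlapping transcript
    intervals are merged and the covered fraction is merged bases over
    transcript length. Returns ``(fraction, hits)``.
    """
    if not seq:
        raise InputError("cannot compute repeat coverage of an empty sequence")
    seq = seq.upper()
    hits: list[RepeatHit] = []
    for entry in repeat_lib:
        for h in _entry_hits(seq, entry, params, scoring):
            hits.append(h._replace(transcript_id=transcript_id))
    covered = sum(e - s for s, e in merge_intervals([(h.q_start, h.q_end) for h in hits]))
    return covered / len(seq), hits


def is_high_copy_repeat(
    fraction: float, threshold: float = DEFAULT_REPEAT_THRESHOLD
) -> bool:
    """True iff the covered fraction strictly exceeds the threshold
    ("more than 80% covered")."""
    if not (0.0 <= fraction <= 1.0):
        raise InputError(f"fraction {fraction} outside [0, 1]")
    return fraction > threshold
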