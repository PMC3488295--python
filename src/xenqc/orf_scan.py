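"""Longest-ORF detection and transcript completeness classification.

Gene-model transcripts inferred from a gapped genome assembly are often
incomplete: the open reading frame (ORF) may lack its start codon, its stop
codon, or both, and the flanking untranslated regions (UTRs) may be absent.
This module finds the longest ATG-initiated ORF in each transcript and
assigns exactly one completeness class per transcript, in decreasing
severity: high-copy repeat, ORF truncated at both ends, truncated 5',
truncated 3', then the four "complete ORF" subclasses distinguished by
which UTRs are present. Tallies of these classes summarise the quality of
an entire gene-model set and are comparable across assembly versions.

Coordinates are 0-based, half-open throughout; the ORF end includes the
stop codon when one is present.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .errors import InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_table = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
_CODON_MAP: dict[str, str] = dict(_table.forward_table)
_CODON_MAP.update({c: "*" for c in _table.stop_codons})

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0) -> str:
    """Translate under the standard nuclear code from the given frame offset.

    A trailing partial codon is dropped. Any codon containing a character
    outside {A,C,G,T} translates to ``'X'`` (gapped assemblies inject Ns and
    a hard failure would be worse); stop codons translate to ``'*'``.
    """
    if offset not in (0, 1, 2):
        raise InputError(f"offset must be 0, 1 or 2, got {offset}")
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(_CODON_MAP.get(seq[i : i + 3], "X"))
    return "".join(out)


@dataclass(frozen=True)
class OrfCall:
    """The longest open reading frame found in a transcript.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    transcript; ``end`` is one past the stop codon when ``has_stop`` is
    true, else one past the last complete codon. ``frame`` is the offset of
    the first codon base from the 5' end of the scanned strand. For
    ``strand == '-'`` the ATG/stop invariants hold on the reverse
    complement of the transcript.
    """

    transcript_id: str
    start: int
    end: int
    has_start: bool
    has_stop: bool
    protein: str
    frame: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF span must be a whole number of codons")
        if self.start < 0 or self.end < self.start:
            raise ValueError("invalid ORF coordinates")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _frame_candidates(seq: str, frame: int) -> list[tuple[int, int, bool]]:
    """All (start, end, has_stop) ATG-anchored candidates in one frame.

    Each ATG extends to the first in-frame stop (end includes the stop) or,
    failing that, to the last complete codon in the frame. Codons containing
    non-ACGT characters are neither start nor stop.
    """
    n = len(seq)
    last_codon_end = frame + 3 * ((n - frame) // 3)
    cands = []
    starts: list[int] = []
    for i in range(frame, n - 2, 3):
        codon = seq[i : i + 3]
        if codon == START_CODON:
            starts.append(i)
        elif codon in STOP_CODONS:
            for s in starts:
                cands.append((s, i + 3, True))
            starts = []
    for s in starts:  # open-ended: no downstream in-frame stop
        cands.append((s, last_codon_end, False))
    return cands


def find_longest_orf(
    seq: str,
    min_len_nt: int = 90,
    scan_reverse: bool = False,
    transcript_id: str = "",
) -> OrfCall | None:
    """Find the longest ATG-initiated reading frame in a transcript.

    The candidate length is measured start to end, including the stop codon
    when present. Candidates shorter than *min_len_nt* are discarded;
    ``None`` means no acceptable ORF. Ties on length are broken by 5'-most
    start, then lowest frame index; with *scan_reverse* both strands are
    scanned (forward wins ties) and minus-strand coordinates are mapped
    back onto the forward transcript.
    """
    if not seq:
        raise InputError("cannot scan an empty sequence")
    seq = seq.upper()
    best: tuple | None = None  # (-length, strand_rank, start, frame, cand)

    def consider(cands, frame, strand, L):
        nonlocal best
        for s, e, has_stop in cands:
            if e - s < min_len_nt:
                continue
            if strand == "+":
                fwd_start, fwd_end = s, e
            else:
                fwd_start, fwd_end = L - e, L - s
            key = (-(e - s), 0 if strand == "+" else 1, fwd_start if strand == "+" else s, frame)
            item = (key, (fwd_start, fwd_end, has_stop, frame, strand, s, e))
            if best is None or key < best[0]:
                best = item

    for frame in (0, 1, 2):
        consider(_frame_candidates(seq, frame), frame, "+", len(seq))
    if scan_reverse:
        rc = reverse_complement(seq)
        for frame in (0, 1, 2):
            consider(_frame_candidates(rc, frame), frame, "-", len(seq))

    if best is None:
        return None
    fwd_start, fwd_end, has_stop, frame, strand, s, e = best[1]
    coding = seq[s:e] if strand == "+" else reverse_complement(seq)[s:e]
    protein = translate(coding)
    if has_stop:
        protein = protein[:-1]
    return OrfCall(
        transcript_id=transcript_id,
        start=fwd_start,
        end=fwd_end,
        has_start=True,
        has_stop=has_stop,
        protein=protein,
        frame=frame,
        strand=strand,
    )


class CompletenessClass(enum.Enum):
    """Mutually exclusive transcript completeness categories.

    Listed in decreasing severity; classification assigns the first class
    whose condition holds, so no transcript falls in more than one.
    """

    HIGH_COPY_REPEAT = "high_copy_repeat"
    TRUNC_BOTH = "orf_truncated_both_ends"
    TRUNC_5 = "orf_truncated_5prime"
    TRUNC_3 = "orf_truncated_3prime"
    COMPLETE_NO_UTRS = "complete_no_utrs"
    COMPLETE_NO_5UTR = "complete_no_5utr"
    COMPLETE_NO_3UTR = "complete_no_3utr"
    COMPLETE_WITH_UTRS = "complete_with_utrs"
    NO_ORF = "no_orf"


#: Classes whose ORF is identifiably complete (start and stop both found).
COMPLETE_CLASSES = (
    CompletenessClass.COMPLETE_NO_UTRS,
    CompletenessClass.COMPLETE_NO_5UTR,
    CompletenessClass.COMPLETE_NO_3UTR,
    CompletenessClass.COMPLETE_WITH_UTRS,
)


@dataclass(frozen=True)
class CompletenessParams:
    """Thresholds for completeness classification.

    repeat_threshold : transcripts with a strictly greater repeat-covered
        fraction are called high-copy repeat (the published rule is "more
        than 80% covered").
    min_upstream_open : nt of stop-free in-frame sequence reaching the 5'
        end required to call a putative 5' truncation when no protein
        evidence is supplied.
    """

    repeat_threshold: float = 0.80
    min_upstream_open: int = 30


def _upstream_open(seq: str, orf: OrfCall) -> bool:
    """True if the in-frame region 5' of the ORF start is stop-free all the
    way to the transcript 5' end (fewer than 3 dangling bases remain)."""
    for i in range(orf.start - 3, -1, -3):
        if seq[i : i + 3] in STOP_CODONS:
            return False
    return True


def classify_completeness(
    seq: str,
    orf: OrfCall | None,
    protein_evidence: Sequence[tuple[int, int]] | None = None,
    repeat_fraction: float | None = None,
    params: CompletenessParams = CompletenessParams(),
) -> CompletenessClass:
    """Assign the single completeness class of a transcript.

    Severity-ordered precedence: high-copy repeat, then 5'/3' ORF
    truncation, then the UTR-presence subclasses. A 3' truncation is the
    absence of a stop codon. A 5' truncation is called either from protein
    evidence (an aligned interval starting strictly upstream of the ORF
    start) or, when no evidence set is supplied, from the heuristic that
    the reading frame is open from the ORF start back to the transcript 5'
    end over at least ``params.min_upstream_open`` nt — a putative call.
    """
    if repeat_fraction is not None and not (0.0 <= repeat_fraction <= 1.0):
        raise InputError(f"repeat_fraction {repeat_fraction} outside [0, 1]")
    if repeat_fraction is not None and repeat_fraction > params.repeat_threshold:
        return CompletenessClass.HIGH_COPY_REPEAT
    if orf is None:
        return CompletenessClass.NO_ORF

    seq = seq.upper()
    trunc3 = not orf.has_stop
    if protein_evidence is not None:
        trunc5 = any(ev_start < orf.start for ev_start, _ in protein_evidence)
    else:
        trunc5 = (
            orf.start >= params.min_upstream_open
            and orf.strand == "+"
            and _upstream_open(seq, orf)
        )
    if trunc5 and trunc3:
        return CompletenessClass.TRUNC_BOTH
    if trunc5:
        return CompletenessClass.TRUNC_5
    if trunc3:
        return CompletenessClass.TRUNC_3

    has_5utr = orf.start > 0
    has_3utr = orf.end < len(seq)
    if has_5utr and has_3utr:
        return CompletenessClass.COMPLETE_WITH_UTRS
    if has_5utr:
        return CompletenessClass.COMPLETE_NO_3UTR
    if has_3utr:
        return CompletenessClass.COMPLETE_NO_5UTR
    return CompletenessClass.COMPLETE_NO_UTRS


@dataclass
class CategoryTally:
    """Counts of items per category, with a conservation check.

    Used both for completeness classes and clone-QC codes.
    """

    label: str
    counts: dict
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError(
                f"tally {self.label!r}: counts sum to "
                f"{sum(self.counts.values())}, expected total {self.total}"
            )

    def count(self, category) -> int:
        return self.counts.get(category, 0)


def tally_classes(
    classes: Iterable[tuple[str, CompletenessClass]], label: str
) -> CategoryTally:
    """Count transcripts per completeness class; duplicate ids are rejected
    so no transcript is reported in more than one category."""
    counts: dict[CompletenessClass, int] = {}
    seen: set[str] = set()
    n = 0
    for tid, cls in classes:
        if tid in seen:
            raise InputError(f"duplicate transcript id {tid!r}")
        seen.add(tid)
        counts[cls] = counts.get(cls, 0) + 1
        n += 1
    return CategoryTally(label=label, counts=counts, total=n)
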