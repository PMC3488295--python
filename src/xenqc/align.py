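"""Pairwise local alignment with affine gaps.

Thin layer over :class:`Bio.Align.PairwiseAligner` (local mode) that
recovers the evidence the QC classifiers need: gapless aligned blocks,
indels with their coordinates and inserted sequence, column identity and
per-sequence coverage. Suitable for cDNA-vs-contig comparisons up to
roughly 20 kb.

Coordinate convention: for ``strand == '-'`` the query was reverse
complemented before alignment and all query coordinates refer to that
reverse complement; target coordinates always refer to the given target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio import Align

from .errors import InputError
from .orf_scan import reverse_complement


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring: a gap of length L costs open + (L-1) x extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -1


INSERTION_IN_QUERY = "insertion_in_query"
DELETION_FROM_QUERY = "deletion_from_query"


class Indel(NamedTuple):
    """A gap in one sequence relative to the other.

    ``q_pos``/``t_pos`` locate the indel (position of the first inserted
    base, or the position the deleted bases would occupy); ``seq`` carries
    the inserted bases for query insertions, empty for deletions.
    """

    q_pos: int
    t_pos: int
    length: int
    kind: str
    seq: str = ""


@dataclass
class PairwiseAlignment:
    """A local alignment of a query against a target.

    ``blocks`` are gapless aligned segments ``(q_start, q_end, t_start,
    t_end)``, strictly increasing on both coordinates. ``identity`` is
    computed over all aligned columns including internal gap columns;
    ``q_cov``/``t_cov`` are the fractions of each sequence inside aligned
    blocks.
    """

    q_id: str
    t_id: str
    blocks: list[tuple[int, int, int, int]]
    indels: list[Indel]
    identity: float
    q_cov: float
    t_cov: float
    strand: str
    score: float
    q_len: int
    t_len: int
    #: query in aligned orientation (reverse complemented when strand '-')
    _query: str = ""

    @property
    def q_start(self) -> int:
        return self.blocks[0][0] if self.blocks else 0

    @property
    def q_end(self) -> int:
        return self.blocks[-1][1] if self.blocks else 0

    @property
    def t_start(self) -> int:
        return self.blocks[0][2] if self.blocks else 0

    @property
    def t_end(self) -> int:
        return self.blocks[-1][3] if self.blocks else 0

    def q_interval_forward(self) -> tuple[int, int]:
        """Aligned query span mapped onto the forward (as-given) query."""
        if self.strand == "+":
            return (self.q_start, self.q_end)
        return (self.q_len - self.q_end, self.q_len - self.q_start)


def _aligner(scoring: Scoring) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )


def _one_strand(query: str, target: str, scoring: Scoring):
    aligner = _aligner(scoring)
    alns = aligner.align(target, query)
    try:
        aln = alns[0]
    except IndexError:
        return None
    t_blocks, q_blocks = aln.aligned
    blocks = [
        (int(qs), int(qe), int(ts), int(te))
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
    ]
    return aln.score, blocks


def _evidence(query: str, target: str, blocks) -> tuple[list[Indel], float]:
    """Indels between consecutive blocks, and column identity."""
    indels: list[Indel] = []
    matches = 0
    aligned_cols = 0
    for qs, qe, ts, te in blocks:
        aligned_cols += qe - qs
        matches += sum(query[qs + k] == target[ts + k] for k in range(qe - qs))
    for (pqs, pqe, pts, pte), (qs, qe, ts, te) in zip(blocks, blocks[1:]):
        q_jump, t_jump = qs - pqe, ts - pte
        if q_jump > 0:
            indels.append(
                Indel(pqe, pte, q_jump, INSERTION_IN_QUERY, query[pqe:qs])
            )
            aligned_cols += q_jump
        if t_jump > 0:
            indels.append(Indel(qs, pte, t_jump, DELETION_FROM_QUERY))
            aligned_cols += t_jump
    identity = matches / aligned_cols if aligned_cols else 0.0
    return indels, identity


def net_indels(aln: PairwiseAlignment, min_block: int = 15) -> list[Indel]:
    """Indels after coalescing alignment micro-blocks.

    A long insertion or deletion is sometimes split by the optimal
    traceback when a chance few-base match inside the gap region is
    profitable; such micro-blocks (shorter than *min_block*, not at the
    alignment ends) are absorbed into the surrounding gap and the gap is
    reported as one net event. A balanced compound gap (equal bases on
    both sides) is not an indel. For net insertions ``seq`` spans the
    whole query jump, so motif checks see the full inserted sequence.
    """
    blocks = aln.blocks
    if len(blocks) < 2:
        return []
    anchors = [blocks[0]]
    anchors += [
        b for b in blocks[1:-1] if (b[1] - b[0]) >= min_block
    ]
    anchors.append(blocks[-1])
    qseq_needed: list[Indel] = []
    for (pqs, pqe, pts, pte), (qs, qe, ts, te) in zip(anchors, anchors[1:]):
        q_jump, t_jump = qs - pqe, ts - pte
        if q_jump > t_jump:
            qseq_needed.append(
                Indel(pqe, pte, q_jump - t_jump, INSERTION_IN_QUERY, aln._query[pqe:qs])
            )
        elif t_jump > q_jump:
            qseq_needed.append(Indel(pqe, pte, t_jump - q_jump, DELETION_FROM_QUERY))
    return qseq_needed


def local_align(
    query: str,
    target: str,
    scoring: Scoring = Scoring(),
    q_id: str = "",
    t_id: str = "",
    both_strands: bool = True,
) -> PairwiseAlignment:
    """Best local alignment of *query* against *target*.

    With *both_strands* the reverse complement of the query is also tried
    and the higher-scoring orientation wins (forward wins ties). As a
    shortcut, a forward alignment already scoring at least 90% of the
    theoretical maximum suppresses the reverse scan.
    """
    if not query or not target:
        raise InputError("cannot align empty sequences")
    query, target = query.upper(), target.upper()

    fwd = _one_strand(query, target, scoring)
    chosen, strand, qseq = fwd, "+", query
    strong = scoring.match * min(len(query), len(target)) * 0.9
    if both_strands and not (fwd and fwd[0] >= strong):
        rc = reverse_complement(query)
        rev = _one_strand(rc, target, scoring)
        if rev and (fwd is None or rev[0] > fwd[0]):
            chosen, strand, qseq = rev, "-", rc
    if chosen is None:
        return PairwiseAlignment(
            q_id, t_id, [], [], 0.0, 0.0, 0.0, "+", 0.0, len(query), len(target),
            _query=query,
        )
    score, blocks = chosen
    indels, identity = _evidence(qseq, target, blocks)
    q_aligned = sum(qe - qs for qs, qe, _, _ in blocks)
    t_aligned = sum(te - ts for _, _, ts, te in blocks)
    return PairwiseAlignment(
        q_id=q_id,
        t_id=t_id,
        blocks=blocks,
        indels=indels,
        identity=identity,
        q_cov=q_aligned / len(query),
        t_cov=t_aligned / len(target),
        strand=strand,
        score=float(score),
        q_len=len(query),
        t_len=len(target),
        _query=qseq,
    )
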