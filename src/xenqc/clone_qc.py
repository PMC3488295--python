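"""Full-insert cDNA clone quality control.

A putatively full-length cDNA clone is judged against the assembled EST
contig of its gene: the clone sequence is locally aligned to candidate
contigs and tested for extent relative to the contig ORF and for
frameshifts, large insertions/deletions, chimerism and sequence
divergence. Each clone receives exactly one code:

====== ==========================================================
``?``  no usable full-insert sequence
CHI    chimeric clone (two segments match different contigs)
FL     full-length
FLq    possibly full-length (ORF covered but divergent)
FLsh   odd short form (large in-frame deletion within the ORF)
FLt3   truncated 3'
FLt5   truncated 5'
FLx    probably non-coding (best contig has no credible ORF)
FS     frame shifted (indel of length not divisible by 3 in the ORF)
IMM    immature/mis-spliced mRNA (retained-intron-like insertion)
====== ==========================================================

Codes are assigned by severity-ordered precedence, so permuting the
candidate contigs never changes the call. Decision thresholds are
package defaults (see :class:`CloneQcParams`); every call records the
triggering evidence in its rationale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import (
    DELETION_FROM_QUERY,
    INSERTION_IN_QUERY,
    Indel,
    PairwiseAlignment,
    Scoring,
    local_align,
    net_indels,
)
from .errors import InputError
from .orf_scan import CategoryTally
from .seqio import SeqRecord


@dataclass(frozen=True)
class ContigReference:
    """An assembled EST contig with its (optional) annotated ORF interval,
    0-based half-open on the contig; ``None`` for a non-coding contig."""

    id: str
    seq: str
    orf_start: int | None = None
    orf_end: int | None = None

    def __post_init__(self) -> None:
        if (self.orf_start is None) != (self.orf_end is None):
            raise ValueError("orf_start and orf_end must be given together")
        if self.orf_start is not None:
            if not (0 <= self.orf_start < self.orf_end <= len(self.seq)):
                raise ValueError(f"contig {self.id!r}: ORF outside sequence")
            if (self.orf_end - self.orf_start) % 3:
                raise ValueError(
                    f"contig {self.id!r}: ORF length not divisible by 3"
                )

    @property
    def has_orf(self) -> bool:
        return self.orf_start is not None


class CloneQcCode(enum.Enum):
    UNKNOWN = "?"
    CHI = "CHI"
    FL = "FL"
    FLq = "FLq"
    FLsh = "FLsh"
    FLt3 = "FLt3"
    FLt5 = "FLt5"
    FLx = "FLx"
    FS = "FS"
    IMM = "IMM"


@dataclass(frozen=True)
class CloneQcCall:
    """One code per clone, with the triggering evidence."""

    code: CloneQcCode
    rationale: str


@dataclass(frozen=True)
class CloneQcParams:
    """Decision thresholds for clone classification.

    All values are package defaults surfaced here for configuration:
    ``max_n_fraction`` above which a clone has no usable sequence;
    ``chimera_seg``/``chimera_identity`` for the two disjoint segments of a
    chimera; ``min_orf_nt`` below which a contig counts as non-coding;
    ``min_intron`` for a retained-intron-like insertion (which must begin
    GT and end AG); ``min_short_del`` for an in-frame deletion calling an
    odd short form; ``fl_identity`` separating full-length from possibly
    full-length.
    """

    max_n_fraction: float = 0.50
    chimera_seg: int = 100
    chimera_identity: float = 0.95
    chimera_max_overlap: int = 20
    min_orf_nt: int = 90
    min_intron: int = 60
    min_short_del: int = 60
    fl_identity: float = 0.97


def align_to_contig(
    cdna: SeqRecord,
    contig: ContigReference,
    scoring: Scoring = Scoring(),
) -> PairwiseAlignment:
    """Optimal local affine-gap alignment of a clone against one contig,
    best strand chosen; blocks and indels are recovered from the traceback."""
    if not cdna.seq or not contig.seq:
        raise InputError("cannot align empty sequences")
    return local_align(
        cdna.seq, contig.seq, scoring, q_id=cdna.id, t_id=contig.id
    )


def detect_frameshifts(
    aln: PairwiseAlignment, orf: tuple[int, int] | None
) -> list[Indel]:
    """Indels inside the contig ORF whose length is not a multiple of 3.

    Indels are taken net of alignment micro-blocks (see
    :func:`xenqc.align.net_indels`), so a long gap split by a chance
    few-base match still counts as a single event.
    """
    if orf is None:
        return []
    orf_start, orf_end = orf
    return [
        ind
        for ind in net_indels(aln)
        if ind.length % 3 and orf_start <= ind.t_pos < orf_end
    ]


def _splice_motif(query: str, ind, wobble: int = 3) -> bool:
    """True if the inserted sequence begins GT and ends AG under some
    placement of the gap.

    When the insertion is flanked by bases identical to its own edges, the
    optimal traceback may slide the gap by a base or two; equivalent
    placements within *wobble* are therefore also inspected.
    """
    for s in range(-wobble, wobble + 1):
        w = query[max(ind.q_pos + s, 0) : ind.q_pos + s + ind.length]
        if len(w) == ind.length and w[:2] == "GT" and w[-2:] == "AG":
            return True
    return False


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 1.0


def _find_chimera(
    alns: Sequence[PairwiseAlignment], params: CloneQcParams
) -> tuple[PairwiseAlignment, PairwiseAlignment] | None:
    """Two near-disjoint clone segments matching different contigs."""
    good = [
        a
        for a in alns
        if a.blocks
        and a.identity >= params.chimera_identity
        and (a.q_end - a.q_start) >= params.chimera_seg
    ]
    good.sort(key=lambda a: (-a.score, a.t_id))
    for i, a in enumerate(good):
        a_lo, a_hi = a.q_interval_forward()
        for b in good[i + 1 :]:
            if b.t_id == a.t_id:
                continue
            b_lo, b_hi = b.q_interval_forward()
            overlap = min(a_hi, b_hi) - max(a_lo, b_lo)
            if overlap <= params.chimera_max_overlap:
                return a, b
    return None


def classify_clone(
    cdna: SeqRecord,
    candidates: Sequence[ContigReference],
    params: CloneQcParams = CloneQcParams(),
    scoring: Scoring = Scoring(),
) -> CloneQcCall:
    """Assign the single QC code of a clone against candidate contigs.

    Precedence (first matching rule wins):
    ``?`` no usable sequence; CHI chimera; FLx best contig non-coding;
    IMM retained-intron-like insertion; FS frameshift in the ORF;
    FLsh large in-frame deletion inside a covered ORF; FLt5/FLt3 ORF end
    missed (a clone truncated at both ends maps to FLt5 — the 5' defect is
    the more damaging one for start-codon-anchored uses); FLq ORF covered
    but divergent; FL otherwise.
    """
    if not candidates:
        raise InputError(f"clone {cdna.id!r}: no candidate contigs")

    if not cdna.seq or _n_fraction(cdna.seq) > params.max_n_fraction:
        return CloneQcCall(
            CloneQcCode.UNKNOWN,
            "no usable sequence (empty or mostly undetermined bases)",
        )

    alns = [align_to_contig(cdna, c, scoring) for c in candidates]
    by_id = {c.id: c for c in candidates}
    best = sorted(alns, key=lambda a: (-a.score, a.t_id))[0]
    contig = by_id[best.t_id]

    chi = _find_chimera(alns, params)
    if chi is not None:
        a, b = chi
        return CloneQcCall(
            CloneQcCode.CHI,
            f"disjoint segments match {a.t_id} ({a.q_end - a.q_start} nt) "
            f"and {b.t_id} ({b.q_end - b.q_start} nt)",
        )

    if not contig.has_orf or (contig.orf_end - contig.orf_start) < params.min_orf_nt:
        return CloneQcCall(
            CloneQcCode.FLx,
            f"best contig {contig.id} has no ORF of >= {params.min_orf_nt} nt",
        )
    orf = (contig.orf_start, contig.orf_end)
    gaps = net_indels(best)

    for ind in gaps:
        if (
            ind.kind == INSERTION_IN_QUERY
            and ind.length >= params.min_intron
            and _splice_motif(best._query, ind)
        ):
            return CloneQcCall(
                CloneQcCode.IMM,
                f"{ind.length} nt GT..AG insertion at contig position "
                f"{ind.t_pos} (retained-intron-like)",
            )

    shifts = detect_frameshifts(best, orf)
    if shifts:
        ind = shifts[0]
        return CloneQcCall(
            CloneQcCode.FS,
            f"{ind.length} nt {ind.kind} at contig position {ind.t_pos} "
            "inside the ORF",
        )

    orf_covered = best.t_start <= orf[0] and best.t_end >= orf[1]
    if orf_covered:
        for ind in gaps:
            if (
                ind.kind == DELETION_FROM_QUERY
                and ind.length % 3 == 0
                and ind.length >= params.min_short_del
                and orf[0] <= ind.t_pos < orf[1]
            ):
                return CloneQcCall(
                    CloneQcCode.FLsh,
                    f"in-frame {ind.length} nt deletion at contig position "
                    f"{ind.t_pos} inside the ORF",
                )
    if best.t_start > orf[0]:
        return CloneQcCall(
            CloneQcCode.FLt5,
            f"alignment starts at contig {best.t_start}, missing the ORF "
            f"5' end at {orf[0]}",
        )
    if best.t_end < orf[1]:
        return CloneQcCall(
            CloneQcCode.FLt3,
            f"alignment ends at contig {best.t_end}, missing the ORF "
            f"3' end at {orf[1]}",
        )
    if best.identity < params.fl_identity:
        return CloneQcCall(
            CloneQcCode.FLq,
            f"ORF covered but identity {best.identity:.3f} < "
            f"{params.fl_identity}",
        )
    return CloneQcCall(
        CloneQcCode.FL,
        f"ORF covered at identity {best.identity:.3f} with no defect",
    )


def qc_summary(
    codes: Iterable[tuple[str, CloneQcCode | CloneQcCall]], set_name: str
) -> CategoryTally:
    """Count clones per QC code; duplicate clone ids are rejected."""
    counts: dict[CloneQcCode, int] = {}
    seen: set[str] = set()
    n = 0
    for clone_id, code in codes:
        if clone_id in seen:
            raise InputError(f"duplicate clone id {clone_id!r}")
        seen.add(clone_id)
        if isinstance(code, CloneQcCall):
            code = code.code
        counts[code] = counts.get(code, 0) + 1
        n += 1
    return CategoryTally(label=set_name, counts=counts, total=n)
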