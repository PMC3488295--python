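"""Labelled synthetic fixtures for every classifier in the package.

Real inputs (gene-model sets, clone collections, assemblies, sequence
records) are large and external; these generators emulate their relevant
structure at desk scale with known ground truth, so classifier recovery
and tally conservation are testable offline.

Transcripts are built UTR5 + ORF + UTR3 from a designed codon skeleton and
then damaged according to the requested defect; every emitted transcript
carries its true completeness class. Construction is verified with a
small, independent ORF enumerator (plain nested scans, not the package's
finder): rejection sampling regenerates the random portions until the
designed ORF is the unique longest one and no chance structure (a longer
spurious ORF, an accidentally open upstream frame) could flip the truth
label. For transcripts that keep a 5' UTR and are not 5'-truncated, an
in-frame stop codon is planted directly upstream of the start codon so
the heuristic 5'-truncation rule cannot fire by chance.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime as dt
import io
import random
from dataclasses import dataclass, field, replace
from typing import Sequence

from Bio import SeqIO as BioSeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .clone_qc import CloneQcCode, CloneQcParams, ContigReference
from .errors import SpecError
from .genome_stats import GapStats
from .orf_scan import STOP_CODONS, CompletenessClass
from .seqio import SeqRecord

_NON_STOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
    - STOP_CODONS
    - {"ATG"}
)

TRANSCRIPT_DEFECTS = (
    "none",
    "drop_5utr",
    "drop_3utr",
    "drop_both",
    "truncate_5",
    "truncate_3_remove_stop",
    "frameshift",
    "repeat_fill",
    "no_orf",
)

CLONE_DEFECTS = (
    "perfect",
    "t5",
    "t3",
    "fs",
    "chi",
    "imm",
    "short_del",
    "low_identity",
    "noncoding_target",
)


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n))


# ---------------------------------------------------------------------------
# independent ORF enumerator used only for construction checks


def _enumerate_orfs(seq: str) -> list[tuple[int, int, bool]]:
    """Every ATG-anchored candidate (start, end, has_stop), by direct scan."""
    out = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        stopped = False
        while j + 3 <= n:
            if seq[j : j + 3] in STOP_CODONS:
                out.append((i, j + 3, True))
                stopped = True
                break
            j += 3
        if not stopped:
            out.append((i, i + 3 * ((n - i) // 3), False))
    return out


def _unique_longest(seq: str, start: int, end: int) -> bool:
    """True if (start, end) is the strictly longest ATG candidate, or ties
    only with itself."""
    target = end - start
    for s, e, _ in _enumerate_orfs(seq):
        if (s, e) != (start, end) and e - s >= target:
            return False
    return True


# ---------------------------------------------------------------------------
# transcripts


@dataclass(frozen=True)
class TranscriptSpec:
    """Blueprint for one synthetic transcript.

    ``orf_codons`` counts all codons including start and stop. Defect
    parameters: ``truncate_nt`` (bases removed from the 5' end, must cut
    into the ORF), ``fs_pos``/``fs_len`` (nt offset within the ORF and
    length of the frameshifting insertion), ``repeat_fraction`` (fraction
    of the transcript filled with repeat-library sequence).
    """

    transcript_id: str
    utr5_len: int = 50
    orf_codons: int = 100
    utr3_len: int = 80
    defect: str = "none"
    truncate_nt: int | None = None
    fs_pos: int | None = None
    fs_len: int | None = None
    repeat_fraction: float | None = None
    seed: int = 0


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    defect: str
    true_class: CompletenessClass


def default_repeat_library(seed: int = 2012) -> list[SeqRecord]:
    """A small deterministic library of 'common repeat' sequences."""
    rng = random.Random(seed)
    return [
        SeqRecord(id=f"rep{i+1}", seq=_random_nt(rng, 400)) for i in range(3)
    ]


def _build_transcript(spec: TranscriptSpec, repeat_lib, max_tries=500):
    if spec.defect not in TRANSCRIPT_DEFECTS:
        raise SpecError(f"unknown transcript defect {spec.defect!r}")
    if spec.defect != "no_orf" and spec.orf_codons < 2:
        raise SpecError("orf_codons must be >= 2 when an ORF is requested")
    if spec.defect == "none" and (spec.utr5_len == 0 or spec.utr3_len == 0):
        raise SpecError("defect 'none' requires both UTRs to be non-empty")

    rng = random.Random(spec.seed)
    L = spec.utr5_len + 3 * spec.orf_codons + spec.utr3_len

    if spec.defect == "no_orf":
        for _ in range(max_tries):
            seq = _random_nt(rng, L)
            cands = _enumerate_orfs(seq)
            if all(e - s < 90 for s, e, _ in cands):
                return seq, CompletenessClass.NO_ORF
        raise SpecError(f"{spec.transcript_id}: could not sample an ORF-free sequence")

    if spec.defect == "repeat_fill":
        frac = spec.repeat_fraction if spec.repeat_fraction is not None else 0.90
        if frac <= 0.82:
            raise SpecError(
                "repeat_fill fraction must exceed 0.82 for an unambiguous "
                "high-copy-repeat label"
            )
        rep = "".join(r.seq for r in repeat_lib)
        k = min(int(round(frac * L)), L)
        while len(rep) < k:
            rep += rep
        seq = rep[:k] + _random_nt(rng, L - k)
        return seq, CompletenessClass.HIGH_COPY_REPEAT

    for _ in range(max_tries):
        inner = _random_codons(rng, spec.orf_codons - 2)
        stop = rng.choice(sorted(STOP_CODONS))
        orf = "ATG" + inner + stop
        utr5 = _random_nt(rng, spec.utr5_len)
        utr3 = _random_nt(rng, spec.utr3_len)

        keeps_5utr_and_start = spec.defect in (
            "none", "drop_3utr", "truncate_3_remove_stop", "frameshift"
        )
        if keeps_5utr_and_start and spec.utr5_len >= 3:
            utr5 = utr5[:-3] + "TAA"  # in-frame upstream stop guard

        if spec.defect == "none":
            seq = utr5 + orf + utr3
            start, end = spec.utr5_len, spec.utr5_len + len(orf)
            truth = CompletenessClass.COMPLETE_WITH_UTRS
        elif spec.defect == "drop_5utr":
            seq = orf + utr3
            start, end = 0, len(orf)
            truth = CompletenessClass.COMPLETE_NO_5UTR
        elif spec.defect == "drop_3utr":
            seq = utr5 + orf
            start, end = spec.utr5_len, spec.utr5_len + len(orf)
            truth = CompletenessClass.COMPLETE_NO_3UTR
        elif spec.defect == "drop_both":
            seq = orf
            start, end = 0, len(orf)
            truth = CompletenessClass.COMPLETE_NO_UTRS
        elif spec.defect == "truncate_5":
            cut = (
                spec.truncate_nt
                if spec.truncate_nt is not None
                else spec.utr5_len + 6
            )
            if cut <= spec.utr5_len:
                raise SpecError("truncate_5 must cut into the ORF")
            cut_orf = cut - spec.utr5_len
            j = -(-(cut_orf + 30) // 3)  # internal ATG codon index
            if spec.orf_codons - 1 - j < 30:
                raise SpecError(
                    f"{spec.transcript_id}: ORF too short for a >=90 nt "
                    "reading frame downstream of the internal ATG"
                )
            orf = orf[: 3 * j] + "ATG" + orf[3 * (j + 1) :]
            seq = (utr5 + orf + utr3)[cut:]
            start = 3 * j - cut_orf
            end = spec.utr5_len + len(orf) - cut
            truth = CompletenessClass.TRUNC_5
        elif spec.defect == "truncate_3_remove_stop":
            kept = orf[:-9]  # drop stop plus two codons
            seq = utr5 + kept
            start, end = spec.utr5_len, spec.utr5_len + len(kept)
            truth = CompletenessClass.TRUNC_3
        elif spec.defect == "frameshift":
            pos = spec.fs_pos if spec.fs_pos is not None else 3 * (spec.orf_codons // 2)
            ins = spec.fs_len if spec.fs_len is not None else 1
            if ins % 3 == 0:
                raise SpecError("frameshift length must not be divisible by 3")
            if not (3 <= pos < 3 * spec.orf_codons - 3):
                raise SpecError("frameshift position must lie inside the ORF")
            head = utr5 + orf[:pos] + _random_nt(rng, ins)
            # downstream is written stop-free in the shifted frame, so the
            # ORF loses its terminator and runs to the transcript end
            offset = (len(head) - spec.utr5_len) % 3
            pad = ""
            if offset:
                while True:
                    pad = _random_nt(rng, 3 - offset)
                    if head[-offset:] + pad not in STOP_CODONS:
                        break
            tail_nt = len(orf) - pos + spec.utr3_len
            n_cod = max((tail_nt - len(pad)) // 3, 10)
            seq = head + pad + _random_codons(rng, n_cod)
            start = spec.utr5_len
            end = start + 3 * ((len(seq) - start) // 3)
            truth = CompletenessClass.TRUNC_3
        else:  # pragma: no cover
            raise SpecError(spec.defect)

        ok = _unique_longest(seq, start, end)
        if ok and truth is CompletenessClass.TRUNC_5:
            # earliest surviving in-frame ATG must be the planted one
            ok = "ATG" not in {
                seq[i : i + 3] for i in range(start % 3, start, 3)
            }
        if ok and truth is CompletenessClass.TRUNC_3:
            # shifted/truncated frame must really be stop-free to the end
            ok = all(
                seq[i : i + 3] not in STOP_CODONS
                for i in range(start, len(seq) - 2, 3)
            )
        if ok:
            return seq, truth
    raise SpecError(
        f"{spec.transcript_id}: rejection sampling failed after {max_tries} tries"
    )


def make_transcripts(
    specs: Sequence[TranscriptSpec],
    repeat_lib: Sequence[SeqRecord] | None = None,
) -> tuple[list[SeqRecord], list[TranscriptTruth]]:
    """Generate transcripts with known completeness classes.

    ``repeat_lib`` is the library that repeat_fill transcripts are built
    from (defaults to :func:`default_repeat_library`); pass the same
    library to the repeat-coverage scan when classifying.
    """
    if repeat_lib is None:
        repeat_lib = default_repeat_library()
    records, truths = [], []
    for spec in specs:
        seq, truth = _build_transcript(spec, repeat_lib)
        records.append(SeqRecord(id=spec.transcript_id, seq=seq))
        truths.append(TranscriptTruth(spec.transcript_id, spec.defect, truth))
    return records, truths


# ---------------------------------------------------------------------------
# clone sets


@dataclass(frozen=True)
class CloneSetSpec:
    """Blueprint for a synthetic full-length clone set.

    One clone is emitted per entry of ``defects``. Defect magnitudes
    default to values strictly beyond the classifier thresholds (the
    unambiguous regime); set ``boundary`` to place the short-deletion
    defect exactly at its threshold, which marks those clones ambiguous.
    """

    defects: Sequence[str]
    utr5: int = 100
    orf_codons: int = 400
    utr3: int = 150
    contigs_per_set: int = 3
    seed: int = 0
    boundary: bool = False


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    defect: str
    true_code: CloneQcCode | None  # None = ambiguous, excluded from scoring
    contig_id: str


_CLONE_TRUTH = {
    "perfect": CloneQcCode.FL,
    "t5": CloneQcCode.FLt5,
    "t3": CloneQcCode.FLt3,
    "fs": CloneQcCode.FS,
    "chi": CloneQcCode.CHI,
    "imm": CloneQcCode.IMM,
    "short_del": CloneQcCode.FLsh,
    "low_identity": CloneQcCode.FLq,
    "noncoding_target": CloneQcCode.FLx,
}


def _make_contig(rng: random.Random, cid: str, utr5: int, orf_codons: int, utr3: int) -> ContigReference:
    orf = "ATG" + _random_codons(rng, orf_codons - 2) + rng.choice(sorted(STOP_CODONS))
    seq = _random_nt(rng, utr5) + orf + _random_nt(rng, utr3)
    return ContigReference(id=cid, seq=seq, orf_start=utr5, orf_end=utr5 + len(orf))


def make_clone_set(
    spec: CloneSetSpec,
    params: CloneQcParams = CloneQcParams(),
) -> tuple[list[ContigReference], list[dict], list[SeqRecord], list[CloneTruth]]:
    """Generate contigs, their ORF sidecar rows, clones and truth labels.

    Returns ``(contigs, orf_rows, clones, truths)`` where ``orf_rows`` are
    dicts with contig_id/orf_start/orf_end for the TSV sidecar. Candidate
    contigs for classification are the full contig list.
    """
    bad = set(spec.defects) - set(CLONE_DEFECTS)
    if bad:
        raise SpecError(f"unknown clone defects: {sorted(bad)}")
    rng = random.Random(spec.seed)

    coding = [
        _make_contig(rng, f"ctg{i+1}", spec.utr5, spec.orf_codons, spec.utr3)
        for i in range(max(spec.contigs_per_set, 1))
    ]
    partner = _make_contig(rng, "ctg_chi_partner", spec.utr5, spec.orf_codons, spec.utr3)
    noncoding = ContigReference(
        id="ctg_noncoding",
        seq=_random_nt(rng, spec.utr5 + 3 * spec.orf_codons + spec.utr3),
    )
    contigs = coding + [partner, noncoding]

    clones: list[SeqRecord] = []
    truths: list[CloneTruth] = []
    for i, defect in enumerate(spec.defects):
        cid = f"clone{i+1:03d}"
        base = coding[i % len(coding)]
        seq = base.seq
        os_, oe = base.orf_start, base.orf_end
        mid = (os_ + oe) // 2 - ((os_ + oe) // 2 - os_) % 3  # codon boundary
        truth: CloneQcCode | None = _CLONE_TRUTH[defect]
        target = base.id

        if defect == "perfect":
            pass
        elif defect == "t5":
            seq = seq[os_ + 60 :]
        elif defect == "t3":
            seq = seq[: oe - 60]
        elif defect == "fs":
            seq = seq[:mid] + seq[mid + 1 :]
        elif defect == "chi":
            seg = max(params.chimera_seg + 50, 300)
            seq = base.seq[:seg] + partner.seq[-seg:]
        elif defect == "imm":
            ins = "GT" + _random_nt(rng, 116) + "AG"  # 120 nt retained intron
            seq = seq[:mid] + ins + seq[mid:]
        elif defect == "short_del":
            d = params.min_short_del if spec.boundary else params.min_short_del + 30
            d += (-d) % 3  # keep in frame
            if spec.boundary and d == params.min_short_del:
                truth = None  # exactly at threshold: ambiguous
            seq = seq[:mid] + seq[mid + d :]
        elif defect == "low_identity":
            n_sub = int(round(0.04 * len(seq)))
            positions = rng.sample(range(5, len(seq) - 5), n_sub)
            chars = list(seq)
            for p in positions:
                chars[p] = rng.choice([c for c in "ACGT" if c != chars[p]])
            seq = "".join(chars)
        elif defect == "noncoding_target":
            seq = noncoding.seq
            target = noncoding.id

        clones.append(SeqRecord(id=cid, seq=seq))
        truths.append(CloneTruth(cid, defect, truth, target))

    orf_rows = [
        {"contig_id": c.id, "orf_start": c.orf_start, "orf_end": c.orf_end}
        for c in contigs
        if c.has_orf
    ]
    return contigs, orf_rows, clones, truths


# ---------------------------------------------------------------------------
# scaffolds


def make_scaffolds(
    section_lens: Sequence[int],
    gap_lens: Sequence[int],
    seed: int = 0,
    scaffold_id: str = "scaffold_1",
) -> tuple[SeqRecord, GapStats]:
    """One scaffold interleaving random sections with N-run gaps, plus its
    true gap statistics computed from the specification."""
    if len(gap_lens) != len(section_lens) - 1:
        raise SpecError("need exactly one gap between consecutive sections")
    if any(l <= 0 for l in section_lens) or any(g <= 0 for g in gap_lens):
        raise SpecError("section and gap lengths must be positive")
    rng = random.Random(seed)
    parts = []
    for i, slen in enumerate(section_lens):
        parts.append(_random_nt(rng, slen))
        if i < len(gap_lens):
            parts.append("N" * gap_lens[i])
    truth = GapStats(
        n_scaffolds=1,
        n_sections=len(section_lens),
        assembled_bases=sum(section_lens),
        gap_bases=sum(gap_lens),
    )
    return SeqRecord(id=scaffold_id, seq="".join(parts)), truth


# ---------------------------------------------------------------------------
# flatfiles


@dataclass(frozen=True)
class FlatfileTruth:
    accession: str
    submit_date: dt.date
    last_author: str
    library_id: str | None


def make_flatfiles(
    n: int,
    authors: Sequence[str],
    date_range: tuple[dt.date, dt.date],
    seed: int = 0,
    libraries: Sequence[str] | None = None,
) -> tuple[str, list[FlatfileTruth]]:
    """Minimal valid GenBank-style flatfile text with controlled AUTHORS
    and Submitted dates, plus the truth table.

    Records are written through Biopython's flatfile writer, so the output
    is well-formed and round-trips through standard parsers.
    """
    if n < 0:
        raise SpecError("n must be non-negative")
    if n > 0 and not authors:
        raise SpecError("need at least one author")
    rng = random.Random(seed)
    lo, hi = date_range
    span = (hi - lo).days
    if span < 0:
        raise SpecError("empty date range")

    bio_records = []
    truths: list[FlatfileTruth] = []
    for i in range(n):
        acc = f"XTQC{i+1:04d}"
        date = lo + dt.timedelta(days=rng.randrange(span + 1))
        last = rng.choice(list(authors))
        library = rng.choice(list(libraries)) if libraries else None
        date_str = date.strftime("%d-%b-%Y").upper()

        rec = BioSeqRecord(
            Seq(_random_nt(rng, 60)),
            id=acc,
            name=acc,
            description="Xenopus tropicalis synthetic cDNA record",
            annotations={
                "molecule_type": "mRNA",
                "date": date_str,
                "accessions": [acc],
                "organism": "Xenopus tropicalis",
                "source": "Xenopus tropicalis",
                "data_file_division": "VRT",
            },
        )
        from Bio.SeqFeature import Reference

        pub = Reference()
        pub.authors = "First,A., Second,B. and " + last
        pub.title = "Synthetic cDNA submission"
        pub.journal = "Unpublished"
        sub = Reference()
        sub.authors = "First,A."
        sub.title = "Direct Submission"
        sub.journal = f"Submitted ({date_str}) Synthetic Institute"
        rec.annotations["references"] = [pub, sub]
        qualifiers = {"organism": ["Xenopus tropicalis"], "mol_type": ["mRNA"]}
        if library:
            qualifiers["clone_lib"] = [library]
        rec.features.append(
            SeqFeature(FeatureLocation(0, 60), type="source", qualifiers=qualifiers)
        )
        bio_records.append(rec)
        truths.append(FlatfileTruth(acc, date, last, library))

    buf = io.StringIO()
    if bio_records:
        BioSeqIO.write(bio_records, buf, "genbank")
    return buf.getvalue(), truths
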