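# Methods

This note documents the models, decision rules, parameters and numerical
choices behind xenqc, and what its synthetic-data tests do and do not
demonstrate about real data.

## ORF detection and transcript completeness

The ORF model is deliberately minimal: start codon ATG only, stops
TAA/TAG/TGA, standard nuclear code, forward-strand scanning by default
(gene-model transcripts are sense-strand; `scan_reverse=True` scans both
strands for raw cDNA input and maps minus-strand coordinates back onto
the forward transcript, with the ATG/stop invariants holding on the
reverse complement). Every ATG in every frame opens a candidate, which
extends to the first in-frame stop (the end coordinate includes the
stop) or, when no stop follows, to the last complete codon of that
frame. The longest candidate wins; ties go to the 5′-most start, then
the lowest frame index, then the forward strand. Coordinates are 0-based
half-open throughout.

Codons containing characters outside {A,C,G,T} are neither start nor
stop and translate to `X`: gapped assemblies inject Ns into gene models,
and refusing such transcripts would bias a completeness survey against
exactly the transcripts it is meant to flag.

`min_len_nt` (default 90, i.e. 30 codons) discards candidates too short
to be credible ORFs, so that transcripts with only incidental ATG–stop
pairs report as ORF-free rather than as tiny complete ORFs. The value is
a package default; nothing in the classification scheme depends on it
beyond the NO_ORF boundary.

Completeness classification is a total function with severity-ordered
precedence, so each transcript lands in exactly one category and tallies
are conservative (counts sum to totals by construction):

- **high-copy repeat** precedes everything, at a strictly-greater-than
  0.80 covered-fraction threshold ("more than 80%" — 0.80 itself does
  not trigger);
- **3′ truncation** is simply `has_stop == False`;
- **5′ truncation** has two modes. With protein evidence (aligned
  intervals on the transcript), any interval starting strictly upstream
  of the ORF start triggers it. Without evidence, a heuristic substitutes:
  the frame upstream of the ATG is open (stop-free) all the way to the
  transcript 5′ end and spans at least `min_upstream_open` = 30 nt — a
  transcript whose 5′ end falls inside a coding region looks exactly
  like this. Heuristic calls are marked *putative* in the CLI report.
  30 nt (10 codons) keeps the false-positive rate low for typical short
  5′ UTRs while catching truncations of any consequence;
- otherwise the presence of 5′/3′ UTR sequence (ORF start > 0, ORF end
  < transcript length) selects among the four complete-ORF subclasses.

NO_ORF is a package-added category for transcripts with no acceptable
ORF; the published category scheme has no such row, so reports list it
separately and fixture tallies reconcile without it.

## Repeat screening

The screen aligns the transcript locally against each library entry on
both strands, accepts hits at ≥80% identity over ≥50 nt (package
defaults — the quotable rule is only the 80% *coverage* threshold),
merges overlapping transcript intervals, and divides covered bases by
transcript length. Multiple copies of one repeat are found by iterated
best-hit masking: after each acceptable hit the covered transcript
interval is masked with a non-nucleotide character and the scan repeats
until the residual score cannot support an acceptable hit. Coverage is
therefore invariant to library order and entry duplication, bounded by
1, and monotone in the hit set.

## Local alignment layer

All local alignment goes through Bio.Align.PairwiseAligner in local mode
with match +1, mismatch −2, gap open −5, gap extend −1 (a gap of length
L costs 5 + (L−1)). The wrapper recovers gapless blocks, indels (with
the inserted query sequence), column identity computed over aligned
columns *including* internal gap columns, and per-sequence coverages.
This identity definition is safe here because every large-gap code (IMM,
FLsh, FS) takes precedence over the identity-band codes (FLq/FL).

Two numerical realities are handled explicitly:

- **Gap placement jitter.** An indel flanked by repeated bases can sit
  at several equivalent positions; tests and motif checks tolerate a
  shift of a few bases rather than pinning one traceback.
- **Micro-block splitting.** A long indel is occasionally split by the
  optimal traceback when a chance ≥3-base match inside the gap region is
  profitable under this scoring. `net_indels` absorbs interior blocks
  shorter than 15 nt into the surrounding gap and reports one net event
  (balanced compound gaps are not indels); all gap-based clone-QC rules
  judge these net events. The retained-intron motif check additionally
  inspects placements within ±3 nt for the GT…AG edges.

As a shortcut, a forward-strand alignment scoring ≥90% of the
theoretical maximum suppresses the reverse-strand scan; a truly
reverse-complemented query can never reach that bar, so the best strand
is still chosen.

## Clone QC

The code set and the evidence axes (extent versus the contig ORF,
frameshifts, divergence, chimerism) follow the published scheme; the
operational thresholds are package choices, surfaced in
`CloneQcParams` and recorded per call in the rationale string:

| parameter | default | role |
|---|---|---|
| max_n_fraction | 0.50 | above this, no usable sequence (`?`) |
| chimera_seg / chimera_identity | 100 nt / 0.95 | each chimera segment |
| chimera_max_overlap | 20 nt | "disjoint" tolerance on the clone |
| min_orf_nt | 90 | below this a contig counts as non-coding (FLx) |
| min_intron | 60 nt | GT…AG insertion calling IMM |
| min_short_del | 60 nt | in-frame deletion calling FLsh |
| fl_identity | 0.97 | FL vs FLq identity band |

Design choices where the scheme is silent: a clone truncated at both
ends maps to FLt5, since 5′ loss is the more damaging defect for
start-codon-anchored uses (morpholino design, expression constructs);
FLq ("possibly full-length") is operationalised purely as the
0.97-identity band, its original criterion being unrecoverable; IMM
detection uses canonical splice dinucleotides on the inserted sequence,
a genome-free proxy for a retained intron. Precedence is total and
candidate order cannot change a call (ties between equally scoring
contigs break on contig id).

Published clone-set tallies are carried as fixtures for arithmetic
checks (failure and FL rates); they are *not* reproduction targets for
the classifier, whose thresholds are not those of the original pipeline.

## Gap statistics

An N-run of at least `min_gap_run` = 10 bases is a gap; shorter runs are
ordinary ambiguous bases, since real assemblies contain isolated N calls
that are not gaps. Sections are the maximal intervals between qualifying
runs; an all-N scaffold has zero sections. Conservation
(assembled + gap = total) holds for every threshold, and raising the
threshold can only merge sections. The mean inter-gap distance is
`assembled_bases / n_sections / 1000` kb, reported to one decimal; for
the v4.1 assembly's printed totals (1.5 Gb, 175,000 sections) this gives
8.6 kb, independent of the N-run convention.

## Accounting

`est_fl_genes` rounds half away from zero (4973 × 0.90 = 4475.7 → 4476).
Unmapped accessions are counted and reported, never dropped. Combining
sets deduplicates clones by accession and genes via the gene map. The
combined full-length-gene estimate is this package's own estimator: the
summed per-set estimates scaled by the gene-level deduplication ratio,
`round(Σ est × |combined genes| / Σ |per-set genes|)`, capped at the
combined distinct-gene count. The original combined figure mixed
explicit per-clone calls with a sampled rate in a way that printed data
do not determine, so it is carried only as fixture data. Gene maps are
local TSV inputs; the package never queries remote databases.

## Submission mining

Parsing delegates to Biopython's GenBank reader after a pre-scan that
verifies every LOCUS has a `//` terminator (so truncated downloads fail
loudly with the record index). The last author comes from the AUTHORS
list of the first non-Direct-Submission reference, falling back to the
Direct Submission reference when no other exists. Author strings are
compared exactly after whitespace trimming — no initial or diacritic
folding — so spelling variants of one investigator remain distinct rows,
as they do in the raw records. Month pooling uses the calendar month of
the extracted date, no time zones; in library mode all records of a
library count at the month of the library's earliest noted date, and
records without a library id fall back to their own dates. Undated and
unattributed records are excluded from series/rankings but returned as
counts, so totals always reconcile.

## Synthetic data: what it emulates, and what it does not

The transcript generator builds UTR5 + ORF + UTR3 from a designed codon
skeleton (internal codons exclude stops and ATG, so the designed reading
is controlled) and then applies one defect. Truth labels are forced to
be computable by construction:

- non-truncated transcripts keeping a 5′ UTR get an in-frame stop planted
  directly upstream of the ATG, so the heuristic 5′-truncation rule
  cannot fire by chance;
- 5′-truncated transcripts carry a single planted internal ATG placed so
  that ≥30 nt of open frame remain upstream after the cut;
- frameshifted transcripts have their downstream sequence written
  stop-free in the shifted frame, so the defect deterministically
  presents as a lost terminator (3′ truncation);
- repeat-filled transcripts embed a contiguous run of library sequence
  of the requested fraction (> 0.82 required, keeping clear of the 0.80
  decision boundary);
- rejection sampling, checked with a small independent ORF enumerator
  (direct nested scans, not the finder under test), regenerates any
  sample in which a chance structure — a longer spurious ORF, a stray
  in-frame ATG — could flip the label.

The clone generator derives clones from coding contigs with defect
magnitudes strictly beyond the classifier thresholds (60 nt truncations,
90 nt in-frame deletion, 120 nt GT…AG insertion, 300 nt chimera halves,
4% substitutions); a boundary mode places the short deletion exactly at
threshold and marks those clones ambiguous, excluded from recovery
scoring, so threshold behaviour is exercised without asserting a side.

Consequently, 100% truth recovery on these fixtures demonstrates that
the classifiers implement their decision rules correctly in the
unambiguous regime. It does not demonstrate performance on real data,
where defects co-occur, magnitudes straddle thresholds, sequencing error
is present, and repeat families diverge; no base-error model or
chromatogram-level realism is attempted.

Problem sizes used in the test suite — ~1,100 random sequences for the
ORF oracle, 216 transcripts and 54 clones for recovery, 100 random
assemblies for gap conservation — are the package's chosen desk-scale
defaults; all are configurable through the generator specs.

## Known limitations

- The heuristic 5′-truncation rule will flag genuine transcripts whose
  5′ UTR happens to be long and stop-free in frame; with protein
  evidence supplied, the evidence rule replaces it.
- Alternative transcripts are not modelled; the longest ORF of the given
  sequence is taken as *the* ORF.
- The repeat screen measures coverage against the supplied library only;
  it neither builds libraries nor classifies repeat families.
- Local alignment is exact O(nm); inputs beyond ~20 kb per sequence pair
  become slow and are outside the intended scale.
- FLq/FL and FLsh boundaries are package conventions; published tallies
  using the original (unrecoverable) criteria are fixtures, not targets.
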