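# xenqc

Quality control and accounting for expressed-sequence resources, built
around the analyses used to assess the *Xenopus* (frog) gene-sequence
collections: gene-model transcripts predicted from a gapped genome
assembly, full-length cDNA clone sets, and the public sequence records
that document them.

## What it computes

**Transcript ORF completeness.** For each transcript the longest open
reading frame is found by scanning all three frames for ATG-initiated
readings extended to the first in-frame stop (TAA/TAG/TGA) or, failing
that, to the last complete codon. Each transcript then receives exactly
one class, in decreasing severity:

1. *high-copy repeat* — more than 80% of the transcript is covered by
   local matches to a repeat library (merged intervals, default cutoffs
   ≥80% identity over ≥50 nt per hit);
2. *ORF truncated both ends* / *5′* / *3′* — a 3′ truncation is the
   absence of a stop codon; a 5′ truncation is called from protein
   evidence aligned upstream of the first ATG, or heuristically when the
   reading frame is open from the ATG back to the transcript 5′ end over
   ≥30 nt;
3. the four *complete ORF* subclasses, distinguished by which UTRs
   (sequence outside the ORF) are present.

The complete-ORF percentage of a transcript set,
`100 × (complete subclasses) / total`, is the headline quality measure
for a gene-model release.

**Full-insert clone QC.** A cDNA clone is locally aligned (affine-gap
Smith–Waterman, both strands) against candidate EST-contig references
and coded by severity-ordered precedence: `?` (no usable sequence), CHI
(chimera: two disjoint ≥100 nt segments at ≥95% identity matching
different contigs), FLx (best contig non-coding), IMM (≥60 nt GT…AG
insertion, a retained-intron proxy), FS (indel of length ≢ 0 mod 3
inside the contig ORF), FLsh (≥60 nt in-frame deletion inside a covered
ORF), FLt5/FLt3 (ORF end missed), FLq (ORF covered, identity <97%), FL
(full-length). From a coded set,
`FL rate = FL / (total − '?')` estimates the full-length fraction among
successfully sequenced clones.

**Assembly gap statistics.** Scaffolds are split at N-runs (≥10 N by
default) into contiguous sections; the mean section length,
`assembled bases / sections`, is the average distance between gaps — the
quantity that decides how often a multi-exon gene locus is interrupted.

**Clone-set accounting.** Distinct accessioned clones are mapped to gene
identifiers (accession → gene TSV), deduplicated within and across sets,
and `est_fl_genes = round(distinct_genes × FL rate)` estimates genes
with a full-length clone. Coverage percentages relate genes-with-data to
an estimated gene complement.

**Submission mining.** GenBank-format flatfiles are mined for the
submission date (`Submitted (DD-MON-YYYY)` in the Direct Submission
reference) and the last author of the first listed publication; monthly
pooling yields discovery-rate time series and last-author ranking
separates the large-scale projects from individual laboratories.

**Synthetic data.** Every classifier has a matching generator producing
labelled transcripts, clone sets, gapped scaffolds and flatfiles with
known ground truth, deterministic under a seed.

## Worked example

```
$ python examples/genome_gap_stats.py
scaffold of 33,220 nt
  sections:        4 (truth 4)
  assembled bases: 33,000
  gap bases:       220
  mean section:    8,250.0 nt
  mean inter-gap:  8.2 kb

v4.1 assembly totals: 1.5 Gb over 175,000 sections -> 8.6 kb between gaps
on average; multi-exon gene loci spanning tens of kb will therefore
routinely contain assembly gaps.
```

The synthetic scaffold's statistics are recovered exactly from its
FASTA-level N-runs; applying the same arithmetic to the printed totals
of the *X. tropicalis* v4.1 assembly gives the 8.6 kb mean inter-gap
distance. The other examples (`examples/*.py`) walk through transcript
completeness classification, clone QC, clone-set accounting and
submission mining the same way, each printing the tally or ranking it
computes and a line on what the numbers mean.

A thin CLI mirrors the library:

```
xenqc orf-scan --fasta models.fa --out classes.tsv --summary tally.json
xenqc clone-qc --cdna clones.fa --contigs contigs.fa --orfs orfs.tsv --out codes.tsv
xenqc genome-gaps --fasta assembly.fa --out stats.json
xenqc mine --flatfile records.gb --months months.tsv --authors authors.tsv
xenqc simulate transcripts --spec spec.json --seed 1 --out fixtures/
```

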