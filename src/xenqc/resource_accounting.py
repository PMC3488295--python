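"""Clone-set to gene accounting.

A physical full-length clone collection is distributed as 96-well plates.
Counting the distinct clones with sequence accessions, mapping those
accessions to gene identifiers, and factoring in the set's full-length
rate yields the number of genes for which the collection holds at least
one (probably) full-length clone. Combining sets deduplicates genes held
in more than one collection. Coverage percentages relate genes with data
to an estimate of the genome's protein-coding gene count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .clone_qc import CloneQcCode
from .errors import InputError
from .orf_scan import CategoryTally

WELLS_PER_PLATE = 96


@dataclass(frozen=True)
class CloneRecord:
    """One arrayed clone: its set, species, sequence accession (if any)
    and QC code (if analyzed)."""

    clone_id: str
    set_name: str
    species: str
    accession: str | None = None
    qc_code: CloneQcCode | None = None


@dataclass(frozen=True)
class GeneMap:
    """Accession -> gene id mapping (many accessions to one gene)."""

    pairs: Mapping[str, str]

    def gene(self, accession: str) -> str | None:
        return self.pairs.get(accession)


@dataclass(frozen=True)
class SetSummary:
    set_name: str
    plates: int
    wells: int
    distinct_clones: int
    distinct_genes: int
    est_fl_genes: int
    unmapped_accessions: int

    def __post_init__(self) -> None:
        if self.wells != self.plates * WELLS_PER_PLATE:
            raise ValueError("wells must equal plates x 96")
        if not (
            self.distinct_genes <= self.distinct_clones <= self.wells
            and self.est_fl_genes <= self.distinct_genes
        ):
            raise ValueError(f"inconsistent summary for {self.set_name!r}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_set(
    clones: Sequence[CloneRecord],
    gene_map: GeneMap,
    plates: int,
    fl_rate: float,
    set_name: str | None = None,
) -> SetSummary:
    """Account one clone set: distinct accessioned clones, distinct mapped
    genes, and the estimated number of genes with a full-length clone
    (``round(distinct_genes x fl_rate)``, half away from zero). Accessions
    absent from the gene map are counted, never silently dropped."""
    if plates <= 0:
        raise InputError("plates must be positive")
    if not (0.0 <= fl_rate <= 1.0):
        raise InputError(f"fl_rate {fl_rate} outside [0, 1]")
    accessioned = {c.clone_id for c in clones if c.accession}
    accessions = {c.accession for c in clones if c.accession}
    genes = {gene_map.gene(a) for a in accessions} - {None}
    unmapped = sum(1 for a in accessions if gene_map.gene(a) is None)
    name = set_name if set_name is not None else (clones[0].set_name if clones else "")
    return SetSummary(
        set_name=name,
        plates=plates,
        wells=plates * WELLS_PER_PLATE,
        distinct_clones=len(accessioned),
        distinct_genes=len(genes),
        est_fl_genes=_round_half_away(len(genes) * fl_rate),
        unmapped_accessions=unmapped,
    )


def fl_rate_from_qc(tally: CategoryTally, mode: str = "explicit") -> float:
    """Full-length rate among successfully sequenced clones:
    FL / (total - unsequenced), where the ``?`` code marks clones lacking
    a full-insert sequencing result."""
    if mode != "explicit":
        raise InputError(f"unknown mode {mode!r}")
    if tally.total <= 0:
        raise InputError("empty tally")
    sequenced = tally.total - tally.count(CloneQcCode.UNKNOWN)
    if sequenced <= 0:
        raise InputError("no sequenced clones in tally")
    return tally.count(CloneQcCode.FL) / sequenced


def combine_sets(
    summaries: Sequence[SetSummary],
    clone_tables: Sequence[Sequence[CloneRecord]],
    gene_map: GeneMap,
    set_name: str = "(combined sources)",
) -> SetSummary:
    """Combine same-species clone sets, deduplicating clones (by accession)
    and genes (via the gene map) across sets.

    The combined full-length-gene estimate scales the summed per-set
    estimates by the gene-level deduplication ratio, capped at the
    combined distinct-gene count; a single set passes through unchanged.
    """
    if not summaries or len(summaries) != len(clone_tables):
        raise InputError("summaries and clone tables must align")
    if len(summaries) == 1:
        return summaries[0]
    species = {c.species for table in clone_tables for c in table}
    if len(species) > 1:
        raise InputError(f"species mismatch across sets: {sorted(species)}")

    all_clones = [c for table in clone_tables for c in table]
    accessions = {c.accession for c in all_clones if c.accession}
    genes = {gene_map.gene(a) for a in accessions} - {None}
    unmapped = sum(1 for a in accessions if gene_map.gene(a) is None)
    plates = sum(s.plates for s in summaries)
    sum_genes = sum(s.distinct_genes for s in summaries)
    sum_est = sum(s.est_fl_genes for s in summaries)
    est = (
        min(_round_half_away(sum_est * len(genes) / sum_genes), len(genes))
        if sum_genes
        else 0
    )
    return SetSummary(
        set_name=set_name,
        plates=plates,
        wells=plates * WELLS_PER_PLATE,
        distinct_clones=len(accessions),
        distinct_genes=len(genes),
        est_fl_genes=est,
        unmapped_accessions=unmapped,
    )


def coverage_percent(genes_with_data: int, gene_total_estimate: int) -> float:
    """Percentage of the estimated gene complement with data, 1 decimal."""
    if gene_total_estimate <= 0:
        raise InputError("gene_total_estimate must be positive")
    if genes_with_data > gene_total_estimate:
        raise InputError("genes_with_data exceeds the gene total estimate")
    return round(100.0 * genes_with_data / gene_total_estimate, 1)
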