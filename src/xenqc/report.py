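"""Report rendering and packaged reference tables.

Renders completeness and clone-QC tallies as aligned text tables plus a
machine-readable summary, and computes the headline percentages: the
complete-ORF percentage of a gene-model set, and a clone set's failure
and full-length-of-sequenced rates. Percentages are rounded to the
nearest integer for display; raw fractions are retained in the summary
dict, which is the stable interface.

The module also ships, as fixtures, the published QC tallies for the two
Xenopus tropicalis full-length clone projects (Wellcome/Sanger and
IMAGE/XGC), the gene-model completeness tallies for the v4.1 and v7.1
genome assemblies, and the clone-set gene-accounting rows. These are
reference data for arithmetic and reconciliation checks, not outputs of
the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .clone_qc import CloneQcCode
from .errors import InputError
from .orf_scan import COMPLETE_CLASSES, CategoryTally, CompletenessClass
from .resource_accounting import fl_rate_from_qc

# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class FixtureTable:
    """A labelled reference tally whose rows must sum to its total."""

    name: str
    rows: Mapping
    total: int

    def __post_init__(self) -> None:
        if sum(self.rows.values()) != self.total:
            raise ValueError(f"fixture {self.name!r} does not reconcile")

    def tally(self) -> CategoryTally:
        return CategoryTally(self.name, dict(self.rows), self.total)


_C = CompletenessClass
_Q = CloneQcCode

COMPLETENESS_FIXTURES: dict[str, FixtureTable] = {
    "gene_models_v41": FixtureTable(
        "gene_models_v41",
        {
            _C.HIGH_COPY_REPEAT: 868,
            _C.TRUNC_BOTH: 3536,
            _C.TRUNC_5: 2307,
            _C.TRUNC_3: 9594,
            _C.COMPLETE_NO_UTRS: 4020,
            _C.COMPLETE_NO_5UTR: 399,
            _C.COMPLETE_NO_3UTR: 3230,
            _C.COMPLETE_WITH_UTRS: 3699,
        },
        27_653,
    ),
    "gene_models_v71": FixtureTable(
        "gene_models_v71",
        {
            _C.HIGH_COPY_REPEAT: 1056,
            _C.TRUNC_BOTH: 486,
            _C.TRUNC_5: 1262,
            _C.TRUNC_3: 2798,
            _C.COMPLETE_NO_UTRS: 4610,
            _C.COMPLETE_NO_5UTR: 2920,
            _C.COMPLETE_NO_3UTR: 3396,
            _C.COMPLETE_WITH_UTRS: 26_908,
        },
        43_436,
    ),
}

QC_FIXTURES: dict[str, FixtureTable] = {
    "wellcome_sanger_qc": FixtureTable(
        "wellcome_sanger_qc",
        {
            _Q.UNKNOWN: 2772,
            _Q.CHI: 64,
            _Q.FL: 4585,
            _Q.FLq: 256,
            _Q.FLsh: 147,
            _Q.FLt3: 715,
            _Q.FLt5: 335,
            _Q.FLx: 228,
            _Q.FS: 96,
            _Q.IMM: 18,
        },
        9216,
    ),
    "image_xgc_qc": FixtureTable(
        "image_xgc_qc",
        {
            _Q.UNKNOWN: 4,
            _Q.CHI: 8,
            _Q.FL: 1795,
            _Q.FLq: 31,
            _Q.FLsh: 35,
            _Q.FLt3: 0,
            _Q.FLt5: 3,
            _Q.FLx: 3,
            _Q.FS: 37,
            _Q.IMM: 4,
        },
        1920,
    ),
}

#: Published clone-set gene accounting rows:
#: (species, source, plates, wells, distinct clones, distinct genes,
#:  estimated genes with a full-length cDNA).
CLONE_SET_ROWS: list[tuple[str, str, int, int, int, int, int]] = [
    ("Xenopus tropicalis", "IMAGE/XGC", 54, 5184, 5165, 4973, 4476),
    ("Xenopus tropicalis", "Wellcome/Sanger", 96, 9216, 5293, 4911, 3904),
    ("Xenopus tropicalis", "(combined sources)", 150, 14_400, 10_458, 7681, 6619),
    ("Xenopus laevis", "IMAGE/XGC", 104, 9984, 9671, 9256, 8381),
]


def fixture_tally(name: str) -> CategoryTally:
    """Look up a packaged fixture tally by name."""
    for group in (COMPLETENESS_FIXTURES, QC_FIXTURES):
        if name in group:
            return group[name].tally()
    raise KeyError(name)


# ---------------------------------------------------------------------------
# rendering

_COMPLETENESS_ORDER = [
    _C.HIGH_COPY_REPEAT,
    _C.TRUNC_BOTH,
    _C.TRUNC_5,
    _C.TRUNC_3,
    _C.COMPLETE_NO_UTRS,
    _C.COMPLETE_NO_5UTR,
    _C.COMPLETE_NO_3UTR,
    _C.COMPLETE_WITH_UTRS,
    _C.NO_ORF,
]

_QC_ORDER = [
    _Q.UNKNOWN, _Q.CHI, _Q.FL, _Q.FLq, _Q.FLsh,
    _Q.FLt3, _Q.FLt5, _Q.FLx, _Q.FS, _Q.IMM,
]


def _render(tally: CategoryTally, order) -> str:
    lines = [f"# {tally.label}\ttotal={tally.total}"]
    for cat in order:
        if cat is _C.NO_ORF and tally.count(cat) == 0:
            continue  # artifact-added category, shown only when populated
        lines.append(f"{cat.value}\t{tally.count(cat)}")
    return "\n".join(lines) + "\n"


def render_completeness_report(tally: CategoryTally) -> tuple[str, dict]:
    """Completeness tally in severity order plus the complete-ORF
    percentage (the four complete subclasses over the total, nearest
    integer). Returns ``(text, summary)``."""
    if tally.total <= 0:
        raise InputError("empty tally")
    complete = sum(tally.count(c) for c in COMPLETE_CLASSES)
    frac = complete / tally.total
    text = _render(tally, _COMPLETENESS_ORDER)
    summary = {
        "label": tally.label,
        "total": tally.total,
        "counts": {c.value: tally.count(c) for c in _COMPLETENESS_ORDER},
        "complete_orf_transcripts": complete,
        "complete_orf_fraction": frac,
        "complete_orf_percent": round(100 * frac),
    }
    return text, summary


def render_qc_report(tally: CategoryTally) -> tuple[str, dict]:
    """Clone-QC tally plus failure percentage (unsequenced over total,
    nearest integer) and the full-length rate among sequenced clones."""
    if tally.total <= 0:
        raise InputError("empty tally")
    failure = tally.count(_Q.UNKNOWN) / tally.total
    fl_rate = fl_rate_from_qc(tally)
    text = _render(tally, _QC_ORDER)
    summary = {
        "label": tally.label,
        "total": tally.total,
        "counts": {c.value: tally.count(c) for c in _QC_ORDER},
        "failure_fraction": failure,
        "failure_percent": round(100 * failure),
        "fl_of_sequenced_fraction": fl_rate,
        "fl_of_sequenced_percent": round(100 * fl_rate),
    }
    return text, summary


def _parse(text: str, lookup) -> CategoryTally:
    lines = [l for l in text.strip().splitlines() if l.strip()]
    head = lines[0]
    if not head.startswith("# "):
        raise InputError("report text lacks its header line")
    label, _, tot = head[2:].partition("\ttotal=")
    counts = {}
    for line in lines[1:]:
        key, _, val = line.partition("\t")
        counts[lookup(key)] = int(val)
    return CategoryTally(label, counts, int(tot))


def parse_completeness_report(text: str) -> CategoryTally:
    """Inverse of :func:`render_completeness_report` (lossless rendering)."""
    return _parse(text, CompletenessClass)


def parse_qc_report(text: str) -> CategoryTally:
    """Inverse of :func:`render_qc_report`."""
    return _parse(text, CloneQcCode)
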