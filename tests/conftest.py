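"""Shared fixtures: synthetic data sets generated once per session."""

from __future__ import annotations

import pytest

import xenqc as xq
from xenqc.synthetic_data import CLONE_DEFECTS, TRANSCRIPT_DEFECTS

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str, min_len_nt: int):
    """Independent oracle: enumerate every ATG-anchored candidate by
    direct scanning and pick the longest (ties: 5'-most start).

    Returns (start, end, has_stop) or None.
    """
    seq = seq.upper()
    n = len(seq)
    best = None
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j, end, has_stop = i, None, False
        while j + 3 <= n:
            if seq[j : j + 3] in STOPS:
                end, has_stop = j + 3, True
                break
            j += 3
        if end is None:
            end = i + 3 * ((n - i) // 3)
        if end - i >= min_len_nt:
            key = (-(end - i), i)
            if best is None or key < best[0]:
                best = (key, (i, end, has_stop))
    return best[1] if best else None


@pytest.fixture(scope="session")
def repeat_library():
    return xq.default_repeat_library()


@pytest.fixture(scope="session")
def transcript_recovery(repeat_library):
    """>=200 labelled transcripts classified through the full pipeline
    (repeat coverage -> longest ORF -> completeness class)."""
    specs = []
    i = 0
    for rep in range(24):
        for defect in TRANSCRIPT_DEFECTS:
            specs.append(
                xq.TranscriptSpec(
                    transcript_id=f"t{i:04d}", defect=defect, seed=20_000 + i
                )
            )
            i += 1
    records, truths = xq.make_transcripts(specs, repeat_library)
    calls = {}
    for rec in records:
        frac, _ = xq.repeat_coverage(rec.seq, repeat_library, transcript_id=rec.id)
        orf = xq.find_longest_orf(rec.seq, transcript_id=rec.id)
        calls[rec.id] = xq.classify_completeness(rec.seq, orf, None, frac)
    return records, truths, calls


@pytest.fixture(scope="session")
def clone_set():
    """A >=50-clone synthetic set covering every defect, with contigs."""
    defects = list(CLONE_DEFECTS) * 6  # 54 clones
    spec = xq.CloneSetSpec(defects=defects, seed=77)
    return xq.make_clone_set(spec)


@pytest.fixture(scope="session")
def clone_recovery(clone_set):
    contigs, _, clones, truths = clone_set
    calls = {rec.id: xq.classify_clone(rec, contigs) for rec in clones}
    return truths, calls
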