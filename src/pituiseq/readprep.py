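"""Read trimming and blocklist filtering for 3'-anchored libraries.

QuantSeq reads run through the polyA tail into the sequencing adapter, so
a read's 3' end is a mixture of A's and (possibly truncated) adapter that
generic trimmers miss. Trimming here removes, from the 3' end, the
earliest-starting of (a) an adapter match or (b) a polyA run that extends
to the read end or into an adapter match (including short terminal adapter
fragments left by read-length truncation), then strips the fixed 12-nt
random primer prefix. Reads are kept only if strictly longer than 36 nt
afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import FormatError
from .io import FastqRecord, revcomp

MIN_KEPT_LEN = 37  # strictly longer than 36 nt
PREFIX_TRIM = 12


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    qualities: str
    trim_reason: str  # polyA | adapter | polyA_in_adapter | none
    kept: bool


def _adapter_match(seq: str, adapter: str, min_match: int = 10, max_mismatch_frac: float = 0.1):
    """Leftmost position where a >=min_match-nt adapter prefix aligns with
    at most ``max_mismatch_frac`` mismatches. Returns None if absent."""
    n = len(seq)
    for i in range(n - min_match + 1):
        m = min(len(adapter), n - i)
        mism = sum(a != b for a, b in zip(seq[i : i + m], adapter[:m]))
        if mism <= max_mismatch_frac * m:
            return i
    return None


def _terminal_fragment(seq: str, adapter: str) -> int:
    """Length of the longest exact adapter prefix terminating the read."""
    for m in range(min(len(seq), len(adapter)), 0, -1):
        if seq.endswith(adapter[:m]):
            return m
    return 0


def _polya_run(seq: str, boundary: int, min_frac: float = 0.9, mismatch_penalty: int = 4) -> int:
    """PolyA run ending at ``boundary``: the score-maximizing extent
    (match +1, mismatch -``mismatch_penalty``) that keeps >=min_frac A
    content and starts on an A. The penalty stops the run at the tail
    boundary instead of swallowing occasional genomic A's, while still
    crossing isolated errors inside a long tail. Returns length (0 if none).
    """
    best, best_score = 0, 0
    n_a = 0
    score = 0
    for k in range(1, boundary + 1):
        if seq[boundary - k] == "A":
            n_a += 1
            score += 1
            if score > best_score and n_a >= min_frac * k:
                best, best_score = k, score
        else:
            score -= mismatch_penalty
    return best


def trim_read(
    raw: FastqRecord,
    adapter: str,
    polya_min_run: int = 8,
    prefix_trim: int = PREFIX_TRIM,
    min_len: int = MIN_KEPT_LEN,
) -> TrimmedRead:
    """Trim polyA tail and adapter from a raw read's 3' end.

    Exact terminal adapter fragments of >=5 nt are treated as adapter
    matches on their own; shorter fragments count only when preceded by a
    qualifying polyA run (the truncated-adapter case).
    """
    if not adapter:
        raise FormatError("adapter must be non-empty")
    seq, qual = raw.sequence, raw.qualities
    if len(seq) != len(qual):
        raise FormatError(f"{raw.read_id}: sequence/quality length mismatch")

    a_start = _adapter_match(seq, adapter)
    frag = 0
    if a_start is None:
        frag = _terminal_fragment(seq, adapter)
        if frag >= 5:
            a_start = len(seq) - frag

    boundary = a_start if a_start is not None else len(seq)
    run = _polya_run(seq, boundary)

    cut = None
    reason = "none"
    if run >= polya_min_run:
        cut = boundary - run
        reason = "polyA_in_adapter" if a_start is not None else "polyA"
    elif a_start is not None:
        cut = a_start
        reason = "adapter"
    elif 1 <= frag < 5:
        # truncated adapter too short to match alone: accept only behind a polyA run
        run = _polya_run(seq, len(seq) - frag)
        if run >= polya_min_run:
            cut = len(seq) - frag - run
            reason = "polyA_in_adapter"

    if cut is None:
        cut = len(seq)
    trimmed_seq = seq[prefix_trim:cut]
    trimmed_qual = qual[prefix_trim:cut]
    kept = len(trimmed_seq) >= min_len
    return TrimmedRead(raw.read_id, trimmed_seq, trimmed_qual, reason, kept)


def trim_reads(reads, adapter: str, **kwargs) -> list[TrimmedRead]:
    return [trim_read(r, adapter, **kwargs) for r in reads]


def filter_blocklist(
    reads, blocklist: dict[str, str], k: int = 25
) -> tuple[list, dict[str, int]]:
    """Remove reads sharing any exact k-mer with a blocklist sequence.

    Both strands of each blocklist entry are indexed. Returns the kept
    reads and a per-entry removal log.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if not blocklist:
        warnings.warn("empty blocklist: no reads removed", stacklevel=2)
        return list(reads), {}

    index: dict[str, str] = {}
    for name, seq in blocklist.items():
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                index.setdefault(s[i : i + k], name)

    kept = []
    removed: dict[str, int] = {name: 0 for name in blocklist}
    for read in reads:
        seq = read.sequence
        hit = None
        for i in range(len(seq) - k + 1):
            hit = index.get(seq[i : i + k])
            if hit is not None:
                break
        if hit is None:
            kept.append(read)
        else:
            removed[hit] += 1
    return kept, removed
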