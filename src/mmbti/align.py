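"""Whole-read and half-read alignment under a fixed edit-distance threshold.

Reads with more than ``max_err`` (default 4) differences from the reference —
counting mismatches and 1-bp insertions/deletions as unit-cost edits — are
considered unmapped.  Unmapped reads are split at the midpoint and each half
is re-aligned under the same threshold; reads with exactly one uniquely
mapping half become anchors for breakpoint clustering.

Placement candidates come from exact 20-mer seeds sampled across the read at
a 5-base stride and verified by banded edit distance (edlib).  Any placement
within 4 edits of a >=125 bp read leaves an exact segment of at least 24 bp,
which always contains such a seed, so the seed stage is lossless for whole
reads at the default threshold; an ``exhaustive`` mode scans the full
reference instead and serves as the reference behaviour at small scale.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import edlib

from .io import GenomicInterval, ReadRecord, ReferenceGenome, revcomp

DEFAULT_MAX_ERR = 4
SEED_LEN = 20
SEED_STRIDE = 5
_CONTIG_PAD = 100  # N-run separating contigs in the concatenated index


@dataclass(frozen=True, slots=True)
class Alignment:
    read_id: str
    interval: GenomicInterval
    strand: str
    edit_distance: int
    unique: bool


@dataclass(slots=True)
class AnchoredRead:
    """An unmapped read plus the placement of its uniquely mapping half.

    The read sequence is normalized to the reference forward strand; ``side``
    is 'L' when the 5' half is the mapped (anchor) half, 'R' when the 3' half
    is.
    """

    read: ReadRecord
    side: str
    anchor: GenomicInterval
    half_len: int


class ReferenceIndex:
    """Exact-seed index over a reference (20-mers at every position)."""

    def __init__(self, ref: ReferenceGenome, seed_len: int = SEED_LEN):
        self.ref = ref
        self.seed_len = seed_len
        pad = "N" * _CONTIG_PAD
        names, offsets, pieces = [], [], []
        cursor = 0
        for name, seq in ref.contigs.items():
            names.append(name)
            offsets.append(cursor)
            pieces.append(seq)
            cursor += len(seq) + _CONTIG_PAD
        self.names = names
        self.offsets = offsets
        self.seq = pad.join(pieces) if len(pieces) > 1 else pieces[0]
        self._index: dict[str, int | list[int]] = {}
        idx = self._index
        s = self.seq
        for i in range(len(s) - seed_len + 1):
            kmer = s[i : i + seed_len]
            v = idx.get(kmer)
            if v is None:
                idx[kmer] = i
            elif isinstance(v, int):
                idx[kmer] = [v, i]
            else:
                v.append(i)

    def to_contig(self, start: int, end: int) -> GenomicInterval | None:
        """Map a concatenated-coordinate interval back to a contig interval."""
        i = bisect_right(self.offsets, start) - 1
        off = self.offsets[i]
        length = len(self.ref.contigs[self.names[i]])
        if end - off > length:  # straddles a pad; cannot be a real placement
            return None
        return GenomicInterval(self.names[i], start - off, end - off)

    def candidate_starts(self, q: str, max_err: int) -> list[int]:
        """Deduplicated candidate placement starts for query ``q`` (forward)."""
        idx = self._index
        k = self.seed_len
        n = len(q)
        seen: set[int] = set()
        out: list[int] = []
        for o in range(0, n - k + 1, SEED_STRIDE):
            v = idx.get(q[o : o + k])
            if v is None:
                continue
            if isinstance(v, int):
                v = (v,)
            for p in v:
                s = p - o
                # bucket starts so indel-shifted seeds collapse to one candidate
                key = s // (max_err + 1)
                if key in seen or (key - 1) in seen or (key + 1) in seen:
                    continue
                seen.add(key)
                out.append(max(0, s))
        return out


def _verify(q: str, index: ReferenceIndex, start: int, max_err: int):
    """Edit distance of ``q`` placed near ``start``; returns (ed, s, e) or None."""
    lo = max(0, start - max_err)
    hi = min(len(index.seq), start + len(q) + max_err)
    res = edlib.align(q, index.seq[lo:hi], mode="HW", task="locations", k=max_err)
    if res["editDistance"] < 0:
        return None
    s, e = res["locations"][0]
    return res["editDistance"], lo + s, lo + e + 1


def _exhaustive_placements(q: str, index: ReferenceIndex, max_err: int):
    res = edlib.align(q, index.seq, mode="HW", task="locations", k=max_err)
    if res["editDistance"] < 0:
        return []
    ed = res["editDistance"]
    placements = []
    last_end = -(10 * max_err)
    for s, e in res["locations"]:
        if s - last_end > max_err:  # distinct placement, not a tie-shift
            placements.append((ed, s, e + 1))
        last_end = e
    return placements


def align_read(
    read: ReadRecord,
    index: ReferenceIndex,
    max_err: int = DEFAULT_MAX_ERR,
    exhaustive: bool = False,
    fast: bool = False,
) -> Alignment | None:
    """Best placement of a read on either strand, or None when unmapped.

    ``unique`` is False when two placements (possibly on different strands)
    tie at the best edit distance.  With ``fast=True`` an exact full-length
    match short-circuits the search (uniqueness is then not certified; used
    for bulk whole-read triage where only mapped/unmapped matters).
    """
    best: list[tuple[int, int, int, str]] = []  # (ed, start, end, strand)
    for strand, q in (("+", read.seq), ("-", revcomp(read.seq))):
        if exhaustive:
            hits = [(ed, s, e, strand) for ed, s, e in
                    _exhaustive_placements(q, index, max_err)]
            best.extend(hits)
            continue
        for s in index.candidate_starts(q, max_err):
            if fast and index.seq[s : s + len(q)] == q:
                iv = index.to_contig(s, s + len(q))
                if iv is not None:
                    return Alignment(read.id, iv, strand, 0, True)
            v = _verify(q, index, s, max_err)
            if v is not None:
                best.append((*v, strand))
    if not best:
        return None
    best.sort(key=lambda t: (t[0], t[1]))
    ed, s, e, strand = best[0]
    ties = sum(
        1
        for b in best
        if b[0] == ed and (abs(b[1] - s) > max_err or b[3] != strand)
    )
    iv = index.to_contig(s, e)
    if iv is None:
        return None
    return Alignment(read.id, iv, strand, ed, ties == 0)


def split_and_anchor(
    read: ReadRecord,
    index: ReferenceIndex,
    max_err: int = DEFAULT_MAX_ERR,
    exhaustive: bool = False,
) -> tuple[AnchoredRead | None, str]:
    """Split an unmapped read at the midpoint and anchor by its mapped half.

    Returns ``(anchor, reason)`` where reason is 'ok', 'both_mapped',
    'none_mapped' or 'ambiguous'.  The output read is reverse-complemented
    when the mapped half lies on the minus strand, so side and anchor follow
    the reference-forward convention.
    """
    n = len(read.seq)
    half = n // 2
    h1 = ReadRecord(read.id + "/h1", read.seq[:half], None, read.mate)
    h2 = ReadRecord(read.id + "/h2", read.seq[half:], None, read.mate)
    a1 = align_read(h1, index, max_err, exhaustive=exhaustive)
    a2 = align_read(h2, index, max_err, exhaustive=exhaustive)
    if a1 is not None and a2 is not None:
        return None, "both_mapped"
    if a1 is None and a2 is None:
        return None, "none_mapped"
    mapped, first_half = (a1, True) if a1 is not None else (a2, False)
    if not mapped.unique:
        return None, "ambiguous"
    if mapped.strand == "+":
        seq = read.seq
        side = "L" if first_half else "R"
    else:
        seq = revcomp(read.seq)
        side = "R" if first_half else "L"
    out = ReadRecord(read.id, seq, None, read.mate)
    half_len = half if first_half else n - half
    return AnchoredRead(out, side, mapped.interval, half_len), "ok"
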