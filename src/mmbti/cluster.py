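"""Positional clustering of anchored reads and consensus contig assembly.

Anchored reads whose mapped halves start within one read length of each
other are grouped by single linkage.  A cluster is accepted when its anchors
are all left, all right, or left-then-right; consensus sequences are built
per side by stacking whole reads at the offsets fixed by their anchors and
taking the per-column majority base, and the left/right consensuses of an
LR cluster are merged by local alignment of their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .align import AnchoredRead
from .io import GenomicInterval

# merge-alignment scoring and acceptance gate
MERGE_MATCH = 1
MERGE_MISMATCH = -2
MERGE_GAP = -3
MIN_MERGE_OVERLAP = 10
MIN_MERGE_IDENTITY = 0.90

_BASE_ORDER = "ACGT"  # lexicographic tie-break for consensus columns


@dataclass(slots=True)
class Cluster:
    contig: str
    window: GenomicInterval
    members: list[AnchoredRead]
    pattern: str = "rejected"  # L_only | R_only | LR | rejected

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class ConsensusContig:
    """Column-majority consensus of a one-sided read stack.

    ``left_ref_start`` is the reference coordinate of the first column when
    the left edge is anchored; ``right_ref_end`` the coordinate one past the
    last column when the right edge is anchored.  A merged LR contig carries
    both.
    """

    seq: str
    side: str  # L | R | LR
    per_column_support: list[int]
    left_ref_start: int | None = None
    right_ref_end: int | None = None
    n_reads: int = 0
    ambiguous_columns: list[int] = field(default_factory=list)

    @property
    def anchor_ref_pos(self) -> int:
        if self.side == "R":
            return self.right_ref_end
        return self.left_ref_start


def cluster_anchored(
    anchors: list[AnchoredRead], min_cluster_size: int, link_dist: int
) -> tuple[list[Cluster], int]:
    """Single-linkage clusters of anchors; returns (clusters, n_discarded).

    Anchors are grouped when their mapped halves start within ``link_dist``
    (one read length) of each other on the same contig; groups below
    ``min_cluster_size`` are discarded and counted.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    ordered = sorted(anchors, key=lambda a: (a.anchor.contig, a.anchor.start))
    clusters: list[Cluster] = []
    discarded = 0
    group: list[AnchoredRead] = []

    def _flush() -> None:
        nonlocal discarded
        if not group:
            return
        if len(group) < min_cluster_size:
            discarded += 1
            return
        contig = group[0].anchor.contig
        start = min(a.anchor.start for a in group)
        end = max(a.anchor.end for a in group)
        c = Cluster(contig, GenomicInterval(contig, start, end), list(group))
        c.pattern = accept_cluster(c)
        clusters.append(c)

    for a in ordered:
        if group and (
            a.anchor.contig != group[-1].anchor.contig
            or a.anchor.start - group[-1].anchor.start > link_dist
        ):
            _flush()
            group = []
        group.append(a)
    _flush()
    return clusters, discarded


def accept_cluster(c: Cluster) -> str:
    """Anchoring pattern: all-left, all-right or left-then-right accepted."""
    l_starts = [a.anchor.start for a in c.members if a.side == "L"]
    r_starts = [a.anchor.start for a in c.members if a.side == "R"]
    if l_starts and not r_starts:
        return "L_only"
    if r_starts and not l_starts:
        return "R_only"
    if max(l_starts) <= min(r_starts):
        return "LR"
    return "rejected"


def build_consensus(c: Cluster, side: str) -> ConsensusContig | None:
    """Majority-per-column consensus of the reads anchored on ``side``.

    Reads are stacked at offsets fixed by their anchor coordinates (left
    anchors fix the read start, right anchors the read end); no realignment
    is performed.  Column ties break lexicographically (A<C<G<T) and are
    flagged.  Returns None when the stack has uncovered interior columns
    (inconsistent offsets).
    """
    members = [a for a in c.members if a.side == side]
    if not members:
        return None
    starts = []
    for a in members:
        if side == "L":
            starts.append(a.anchor.start)
        else:
            starts.append(a.anchor.end - len(a.read.seq))
    lo = min(starts)
    hi = max(s + len(a.read.seq) for s, a in zip(starts, members))
    span = hi - lo
    counts = [[0, 0, 0, 0] for _ in range(span)]
    for s, a in zip(starts, members):
        off = s - lo
        for i, base in enumerate(a.read.seq):
            k = _BASE_ORDER.find(base)
            if k >= 0:
                counts[off + i][k] += 1
    seq_chars: list[str] = []
    support: list[int] = []
    ambiguous: list[int] = []
    for col, row in enumerate(counts):
        total = sum(row)
        if total == 0:
            return None  # gap in the stack: offsets inconsistent
        best = max(row)
        k = row.index(best)  # first (lexicographically smallest) maximum
        if row.count(best) > 1:
            ambiguous.append(col)
        seq_chars.append(_BASE_ORDER[k])
        support.append(total)
    return ConsensusContig(
        seq="".join(seq_chars),
        side=side,
        per_column_support=support,
        left_ref_start=lo if side == "L" else None,
        right_ref_end=hi if side == "R" else None,
        n_reads=len(members),
        ambiguous_columns=ambiguous,
    )


def _merge_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MERGE_MATCH
    aligner.mismatch_score = MERGE_MISMATCH
    aligner.open_gap_score = MERGE_GAP
    aligner.extend_gap_score = MERGE_GAP
    return aligner


_ALIGNER = _merge_aligner()


def merge_LR(
    left: ConsensusContig,
    right: ConsensusContig,
    min_overlap: int = MIN_MERGE_OVERLAP,
    min_identity: float = MIN_MERGE_IDENTITY,
) -> ConsensusContig | None:
    """Merge an L and an R consensus at their best local overlap alignment.

    Requires an overlap of at least ``min_overlap`` aligned columns at
    ``min_identity`` identity; otherwise returns None and the pair is
    reported unmerged as a breakpoint pair.
    """
    aln = next(iter(_ALIGNER.align(left.seq, right.seq)), None)
    if aln is None or not len(aln.aligned[0]):
        return None
    lblocks, rblocks = aln.aligned
    matches = 0
    columns = 0
    prev_l = prev_r = None
    for (ls, le), (rs, re) in zip(lblocks, rblocks):
        if prev_l is not None:
            columns += (ls - prev_l) + (rs - prev_r)  # gap columns
        for i in range(le - ls):
            columns += 1
            if left.seq[ls + i] == right.seq[rs + i]:
                matches += 1
        prev_l, prev_r = le, re
    if columns < min_overlap or matches / columns < min_identity:
        return None
    l_start = lblocks[0][0]
    r_start = rblocks[0][0]
    merged_seq = left.seq[:l_start] + right.seq[r_start:]
    support = left.per_column_support[:l_start] + right.per_column_support[r_start:]
    return ConsensusContig(
        seq=merged_seq,
        side="LR",
        per_column_support=support,
        left_ref_start=left.left_ref_start,
        right_ref_end=right.right_ref_end,
        n_reads=left.n_reads + right.n_reads,
    )
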