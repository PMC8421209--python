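"""Candidate insertion extraction, template search and event classification.

A consensus contig is compared back to the reference: the maximal matching
prefix and suffix (tolerating isolated substitutions) pin the two reference
breakpoints, and the interior segment not explained by the reference is the
candidate insertion.  The reverse complement of the insertion is then aligned
locally to the reference within a configurable window (default 100 bp) of the
breakpoints to identify an inverted template; a direct-orientation scan is
kept for classification.

Event classes:

* ``CLSC`` — classic templated insertion: one nearby inverted template
  explains >= 90% of the insertion and the replaced span is shorter than the
  template.
* ``IPI``  — in-place inversion: the replaced span coincides with the
  inverted template interval.
* ``DD``   — direct duplication: a direct-orientation template beats the best
  inverted one.
* ``DQP``  — deletion at a quasi-palindrome.
* ``CM``   — complex, multi-template event.
* ``unresolved`` — breakpoint with no qualifying template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .cluster import ConsensusContig
from .io import GenomicInterval, ReferenceGenome, revcomp

# classification thresholds (operationalized from the event taxonomy)
SINGLE_TEMPLATE_COVERAGE = 0.90
QP_FLANK = 30
QP_MIN_IDENTITY = 0.80
MIN_SEGMENT_LEN = 10

_MISMATCH_LOOKAHEAD = 8   # isolated substitutions tolerated in flank walks
_MIN_ONE_SIDED_FLANK = 12  # exact bases needed to pin an unanchored edge


@dataclass(slots=True)
class SearchConfig:
    """Search parameter regimes.

    ``min_len`` 6 with ``min_cluster_size`` 3 is the sensitivity-benchmark
    regime; 10 bp / 0.80 identity is the quantitative regime and 25 bp /
    0.40 the detailed one (cluster size 3 for tumors, 10 for fibroblasts).
    """

    min_len: int = 10
    min_identity: float = 0.80
    min_cluster_size: int = 3
    template_window: int = 100
    subclonal_fraction: float = 0.30
    avg_coverage: float | None = None
    max_err: int = 4
    dust_threshold: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True, slots=True)
class TemplateMatch:
    interval: GenomicInterval
    orientation: str          # "inverted" | "direct"
    identity: float
    aligned_len: int          # insertion bases explained by the match
    offset_from_insertion: int
    query_start: int = 0      # within the insertion sequence
    query_end: int = 0


@dataclass(slots=True)
class MMBTICall:
    contig: str
    left_bp: int
    right_bp: int
    ins_seq: str
    templates: list[TemplateMatch] = field(default_factory=list)
    event_class: str = "unresolved"
    support: int = 0
    subclonal: bool = False
    junctions: list = field(default_factory=list)
    one_sided: bool = False

    @property
    def replaced_span(self) -> int:
        return self.right_bp - self.left_bp


def _walk_prefix(c: str, ref_seq: str, start: int) -> int:
    """Length of the matching prefix of ``c`` against ref at ``start``.

    Isolated substitutions (consensus errors at low-support columns) are
    walked through when followed by >= 8 further matches; a second nearby
    mismatch stops the walk.
    """
    i, n, m = 0, len(c), len(ref_seq)
    la = _MISMATCH_LOOKAHEAD
    while i < n and start + i < m:
        if c[i] == ref_seq[start + i]:
            i += 1
            continue
        if (
            i + 1 + la <= n
            and start + i + 1 + la <= m
            and c[i + 1 : i + 1 + la] == ref_seq[start + i + 1 : start + i + 1 + la]
        ):
            i += 1 + la
            continue
        break
    return i


def _walk_suffix(c: str, ref_seq: str, end: int) -> int:
    """Mirror of :func:`_walk_prefix` walking leftwards from ``end``."""
    j, n = 0, len(c)
    la = _MISMATCH_LOOKAHEAD
    while j < n and end - 1 - j >= 0:
        if c[n - 1 - j] == ref_seq[end - 1 - j]:
            j += 1
            continue
        if (
            j + 1 + la <= n
            and end - 1 - j - la >= 0
            and c[n - 2 - j - la : n - 1 - j] == ref_seq[end - 2 - j - la : end - 1 - j]
        ):
            j += 1 + la
            continue
        break
    return j


def _longest_suffix_in(window: str, c: str, max_len: int) -> int:
    """Largest m <= max_len with c[-m:] a substring of window (binary search)."""
    lo, hi = 0, max_len
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if window.find(c[len(c) - mid :]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _longest_prefix_in(window: str, c: str, max_len: int) -> int:
    lo, hi = 0, max_len
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if window.find(c[:mid]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return lo


def extract_variant(
    contig: ConsensusContig,
    ref: ReferenceGenome,
    ref_name: str,
    min_len: int = 1,
    window: int = 100,
) -> tuple[int, int, str, bool] | None:
    """Breakpoints and insertion sequence of a consensus contig, or None.

    Returns ``(left_bp, right_bp, ins_seq, one_sided)``; the reference gap
    ``right_bp - left_bp`` is the replaced span (0 for a pure insertion).
    One-edge contigs (unmerged clusters) have the free edge pinned by exact
    substring search near the anchored edge; when that fails the call is
    one-sided (``right_bp == left_bp``, insertion = unexplained tail).
    Calls shorter than ``min_len`` and contigs fully explained by the
    reference yield None.
    """
    c = contig.seq
    ref_seq = ref[ref_name]
    ls, re_ = contig.left_ref_start, contig.right_ref_end
    one_sided = False

    if ls is not None and re_ is None:
        p = _walk_prefix(c, ref_seq, ls)
        if p >= len(c):
            return None
        wlo = ls + p
        whi = min(len(ref_seq), ls + len(c) + window + 60)
        m = _longest_suffix_in(ref_seq[wlo:whi], c[p:], len(c) - p - 1)
        if m >= _MIN_ONE_SIDED_FLANK:
            re_ = wlo + ref_seq[wlo:whi].find(c[len(c) - m :]) + m
        else:
            left_bp = ls + p
            ins = c[p:]
            if len(ins) < min_len:
                return None
            return left_bp, left_bp, ins, True
    elif re_ is not None and ls is None:
        s = _walk_suffix(c, ref_seq, re_)
        if s >= len(c):
            return None
        whi = re_ - s
        wlo = max(0, re_ - len(c) - window - 60)
        m = _longest_prefix_in(ref_seq[wlo:whi], c[: len(c) - s - 1], len(c) - s - 1)
        if m >= _MIN_ONE_SIDED_FLANK:
            ls = wlo + ref_seq[wlo:whi].find(c[:m])
        else:
            right_bp = re_ - s
            ins = c[: len(c) - s]
            if len(ins) < min_len:
                return None
            return right_bp, right_bp, ins, True
    elif ls is None and re_ is None:
        raise ValueError("consensus contig has no anchored edge")

    p = _walk_prefix(c, ref_seq, ls)
    s = _walk_suffix(c, ref_seq, re_)
    s = min(s, len(c) - p)
    left_bp = ls + p
    right_bp = re_ - s
    if right_bp < left_bp:  # over-greedy flanks inside junction homology
        s -= left_bp - right_bp
        if s < 0:
            p += s
            s = 0
            left_bp = ls + p
        right_bp = re_ - s
    ins = c[p : len(c) - s]
    if not ins:
        return None
    if len(ins) < min_len:
        return None
    return left_bp, right_bp, ins, one_sided


def _local_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -3
    a.extend_gap_score = -3
    return a


_ALIGNER = _local_aligner()


def _aln_stats(aln, query: str, target: str):
    qblocks, tblocks = aln.aligned[0], aln.aligned[1]
    if not len(qblocks):
        return None
    matches = columns = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_q is not None:
            columns += (qs - prev_q) + (ts - prev_t)
        for i in range(qe - qs):
            columns += 1
            if query[qs + i] == target[ts + i]:
                matches += 1
        prev_q, prev_t = qe, te
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    return matches / columns, columns, qe - qs, qs, qe, ts, te


def _local_hits(query: str, target: str, limit: int = 40):
    """Stats for up to ``limit`` co-optimal local alignments.

    Co-optimal alignments can sit at different query/target positions (e.g.
    repeated template copies); downstream tie-breaking needs to see them all.
    """
    if not query or not target:
        return []
    alns = _ALIGNER.align(query, target)
    if alns.score <= 0:
        return []
    hits = []
    for i, aln in enumerate(alns):
        if i >= limit:
            break
        stats = _aln_stats(aln, query, target)
        if stats is not None:
            hits.append(stats)
    return hits


def _best_local(query: str, target: str):
    """Best local alignment stats: (identity, columns, qspan, qs, qe, ts, te)."""
    hits = _local_hits(query, target, limit=1)
    return hits[0] if hits else None


def find_template(
    call: MMBTICall, ref: ReferenceGenome, cfg: SearchConfig
) -> TemplateMatch | None:
    """Best inverted template within the search window of the breakpoints.

    Aligns the reverse complement of the insertion locally against the
    reference between ``left_bp - window - len`` and ``right_bp + window +
    len``; the best hit with identity >= ``min_identity`` and >= ``min_len``
    aligned insertion bases is returned (orientation "inverted").  A
    direct-orientation scan is run as well and appended to the call's
    template list for classification.  Without a qualifying inverted hit the
    call stays an unresolved breakpoint (None returned).
    """
    ins = call.ins_seq
    ref_seq = ref[call.contig]
    wlo = max(0, call.left_bp - cfg.template_window - len(ins))
    whi = min(len(ref_seq), call.right_bp + cfg.template_window + len(ins))
    region = ref_seq[wlo:whi]

    hits: dict[str, TemplateMatch] = {}
    for orientation, query in (("inverted", revcomp(ins)), ("direct", ins)):
        candidates = []
        for stats in _local_hits(query, region):
            identity, _cols, qspan, qs, qe, ts, te = stats
            if identity < cfg.min_identity or qspan < cfg.min_len:
                continue
            # report query coords on the insertion itself
            if orientation == "inverted":
                q0, q1 = len(ins) - qe, len(ins) - qs
            else:
                q0, q1 = qs, qe
            iv = GenomicInterval(
                call.contig, wlo + ts, wlo + te,
                "-" if orientation == "inverted" else "+",
            )
            candidates.append(
                TemplateMatch(
                    interval=iv,
                    orientation=orientation,
                    identity=identity,
                    aligned_len=qspan,
                    offset_from_insertion=iv.start - call.left_bp,
                    query_start=q0,
                    query_end=q1,
                )
            )
        if candidates:
            # ties: higher identity, smaller |offset|, leftmost
            candidates.sort(
                key=lambda t: (
                    -t.identity,
                    abs(t.offset_from_insertion),
                    t.interval.start,
                )
            )
            hits[orientation] = candidates[0]
    call.templates = [t for k in ("inverted", "direct") if (t := hits.get(k))]
    return hits.get("inverted")


def resolve_multi_template(
    ins_seq: str,
    ref: ReferenceGenome,
    contig: str,
    left_bp: int,
    right_bp: int,
    window: int = 100,
    min_segment: int = MIN_SEGMENT_LEN,
) -> list[TemplateMatch]:
    """Greedy left-to-right segmentation of an insertion into template copies.

    Repeatedly aligns the unexplained suffix of the insertion (both
    orientations) within the window around the insertion site and takes the
    longest match anchored at the start of the unexplained part; stops when
    fewer than ``min_segment`` bases remain or no anchored match is found.
    """
    ref_seq = ref[contig]
    wlo = max(0, left_bp - window - len(ins_seq))
    whi = min(len(ref_seq), right_bp + window + len(ins_seq))
    region = ref_seq[wlo:whi]
    segments: list[TemplateMatch] = []
    done = 0
    while len(ins_seq) - done >= min_segment and len(segments) < 10:
        rest = ins_seq[done:]
        best = None
        for orientation, query in (("inverted", revcomp(rest)), ("direct", rest)):
            for stats in _local_hits(query, region):
                identity, _cols, qspan, qs, qe, ts, te = stats
                if orientation == "inverted":
                    q0, q1 = len(rest) - qe, len(rest) - qs
                else:
                    q0, q1 = qs, qe
                if q0 > 2 or qspan < min_segment:
                    continue  # not anchored at the unexplained prefix
                if best is None or qspan > best[0]:
                    best = (qspan, orientation, identity, q0, q1, ts, te)
        if best is None:
            break
        qspan, orientation, identity, q0, q1, ts, te = best
        iv = GenomicInterval(
            contig, wlo + ts, wlo + te,
            "-" if orientation == "inverted" else "+",
        )
        segments.append(
            TemplateMatch(
                interval=iv,
                orientation=orientation,
                identity=identity,
                aligned_len=qspan,
                offset_from_insertion=iv.start - left_bp,
                query_start=done + q0,
                query_end=done + q1,
            )
        )
        done += q1
    return segments


def _quasi_palindrome(ref_seq: str, left_bp: int, right_bp: int) -> bool:
    fl = ref_seq[max(0, left_bp - QP_FLANK) : left_bp]
    fr = ref_seq[right_bp : right_bp + QP_FLANK]
    if len(fl) < QP_FLANK // 2 or len(fr) < QP_FLANK // 2:
        return False
    stats = _best_local(fl, revcomp(fr))
    if stats is None:
        return False
    identity, columns = stats[0], stats[1]
    return columns >= QP_FLANK // 2 and identity >= QP_MIN_IDENTITY


def classify_event(call: MMBTICall, ref: ReferenceGenome) -> str:
    """Assign an event class from the call's templates and geometry."""
    ins = call.ins_seq
    ref_seq = ref[call.contig]
    inv = next((t for t in call.templates if t.orientation == "inverted"), None)
    direct = next((t for t in call.templates if t.orientation == "direct"), None)

    if inv is not None and (
        inv.interval.start == call.left_bp and inv.interval.end == call.right_bp
    ):
        return "IPI"
    if direct is not None and (inv is None or direct.identity > inv.identity):
        return "DD"
    if call.replaced_span > len(ins) and _quasi_palindrome(
        ref_seq, call.left_bp, call.right_bp
    ):
        return "DQP"
    inv_cov = inv.aligned_len / len(ins) if inv is not None else 0.0
    if (
        inv is not None
        and inv_cov >= SINGLE_TEMPLATE_COVERAGE
        and call.replaced_span < len(inv.interval)
    ):
        return "CLSC"
    if inv_cov < SINGLE_TEMPLATE_COVERAGE:
        segments = resolve_multi_template(
            ins, ref, call.contig, call.left_bp, call.right_bp
        )
        covered = sum(t.query_end - t.query_start for t in segments)
        if len(segments) >= 2 and covered / len(ins) >= SINGLE_TEMPLATE_COVERAGE:
            call.templates = segments
            return "CM"
    return "unresolved"


def flag_clonality(
    support: int, avg_coverage: float, subclonal_fraction: float = 0.30
) -> bool:
    """Sub-clonal when support / coverage is strictly below the fraction."""
    if avg_coverage <= 0:
        raise ValueError("avg_coverage must be positive")
    return support / avg_coverage < subclonal_fraction
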