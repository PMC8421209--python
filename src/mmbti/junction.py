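"""Microhomology and microhomeology at template-switch junctions.

At a junction the nascent strand leaves one sequence (the donor) and resumes
on another (the acceptor).  Microhomology is the number of uninterrupted
identical bases shared by the donor's 3' end and the sequence immediately
upstream of the switch point on the acceptor, walking 5'-ward from the
junction.  Microhomeology allows exactly one interruption — a single aligned
mismatch or a 1-bp gap on either strand — provided at least one further
matching base is gained beyond it; the reported value is the maximum over
interruption type and placement (the interruption may sit anywhere in the
walk, including at the 3'-most base).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io import ReferenceGenome, revcomp

MH_CAP = 30  # reported lengths are capped; beyond this is not signature-relevant


@dataclass(frozen=True, slots=True)
class JunctionMH:
    junction_index: int
    mh: int
    mheo: int
    interrupted: bool

    def __post_init__(self) -> None:
        if self.mheo < self.mh:
            raise ValueError("mheo must be >= mh")


def _run(a: str, b: str, i: int, j: int) -> int:
    """Matching run length of a[i:], b[j:] (both already 3'->5' ordered)."""
    k = 0
    while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
        k += 1
    return k


def count_microhomology(donor_suffix: str, acceptor_upstream: str) -> int:
    """Uninterrupted matching bases at the junction (longest common suffix)."""
    if not donor_suffix or not acceptor_upstream:
        raise ValueError("junction flanks must be non-empty")
    a = donor_suffix[::-1]
    b = acceptor_upstream[::-1]
    return _run(a, b, 0, 0)


def count_microhomeology(
    donor_suffix: str, acceptor_upstream: str
) -> tuple[int, bool]:
    """Microhomology extended through at most one mismatch or 1-bp gap.

    Returns ``(mheo, interrupted)``.  All placements of the single
    interruption within the walk are tried (aligned mismatch, gap on the
    donor, gap on the acceptor) and the maximum total of matched bases is
    reported; if no placement gains at least one base over the plain
    microhomology, ``mheo == mh`` and ``interrupted`` is False.
    """
    mh = count_microhomology(donor_suffix, acceptor_upstream)
    a = donor_suffix[::-1]
    b = acceptor_upstream[::-1]
    best = mh
    for j in range(mh + 1):
        # aligned mismatch at walk position j
        cand = j + _run(a, b, j + 1, j + 1)
        best = max(best, cand)
        # 1-bp gap: skip one base on the donor, or on the acceptor
        cand = j + _run(a, b, j + 1, j)
        best = max(best, cand)
        cand = j + _run(a, b, j, j + 1)
        best = max(best, cand)
    if best > mh:
        return best, True
    return mh, False


def junction_flanks(
    call, template, ref: ReferenceGenome, cap: int = MH_CAP
) -> list[tuple[str, str]]:
    """Donor-suffix / acceptor-upstream string pairs for a call's junctions.

    Junction 1 is the switch from the reference into the template; its donor
    is the reference upstream of the left breakpoint, and the acceptor
    context is what precedes the copied segment in the copied orientation
    (for an inverted template ending at ``t1`` this is
    ``revcomp(ref[t1 : t1 + cap])``).  Junction 2 is the return to the
    reference: the nascent strand ending in the insertion is the donor and
    the reference upstream of the right breakpoint the acceptor.
    """
    ref_seq = ref[call.contig]
    k = cap + 2
    t0, t1 = template.interval.start, template.interval.end
    donor1 = ref_seq[max(0, call.left_bp - k) : call.left_bp]
    if template.orientation == "inverted":
        acceptor1 = revcomp(ref_seq[t1 : t1 + k])
    else:
        acceptor1 = ref_seq[max(0, t0 - k) : t0]
    donor2 = (ref_seq[max(0, call.left_bp - k) : call.left_bp] + call.ins_seq)[-k:]
    acceptor2 = ref_seq[max(0, call.right_bp - k) : call.right_bp]
    return [(donor1, acceptor1), (donor2, acceptor2)]


def junctions_for_call(call, ref: ReferenceGenome, cap: int = MH_CAP) -> list[JunctionMH]:
    """Per-junction microhomology/microhomeology for a single-template call."""
    if not call.templates:
        return []
    template = call.templates[0]
    out = []
    for idx, (donor, acceptor) in enumerate(
        junction_flanks(call, template, ref, cap)
    ):
        if not donor or not acceptor:
            continue
        mh = min(count_microhomology(donor, acceptor), cap)
        mheo, interrupted = count_microhomeology(donor, acceptor)
        mheo = min(mheo, cap)
        out.append(JunctionMH(idx, mh, max(mheo, mh), interrupted))
    return out


def junction_distribution(calls) -> dict:
    """Histogram of mh and mheo over all resolvable junctions of a call set.

    Calls without a resolved template are excluded and counted separately.
    Returns ``{"mh": Counter, "mheo": Counter, "mean_mh": float | None,
    "mean_mheo": float | None, "n_junctions": int, "n_excluded": int}``.
    """
    mh_counts: Counter = Counter()
    mheo_counts: Counter = Counter()
    excluded = 0
    n = 0
    for call in calls:
        if not call.junctions:
            excluded += 1
            continue
        for j in call.junctions:
            mh_counts[j.mh] += 1
            mheo_counts[j.mheo] += 1
            n += 1
    mean = lambda c: (sum(k * v for k, v in c.items()) / sum(c.values())) if c else None
    return {
        "mh": dict(sorted(mh_counts.items())),
        "mheo": dict(sorted(mheo_counts.items())),
        "mean_mh": mean(mh_counts),
        "mean_mheo": mean(mheo_counts),
        "n_junctions": n,
        "n_excluded": excluded,
    }
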