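"""Benchmark scoring against a truth manifest and paired-sample comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib


@dataclass(slots=True)
class EvaluationResult:
    """TP/FP/FN counts against a planted-insertion manifest.

    recall = TP / (TP + FN); FN = planted - TP; duplicate calls matching an
    already-matched truth count as FP; fp_rate = FP / (TP + FP).
    """

    TP: int
    FP: int
    FN: int

    @property
    def recall(self) -> float | None:
        total = self.TP + self.FN
        return self.TP / total if total else None

    @property
    def fp_rate(self) -> float | None:
        calls = self.TP + self.FP
        return self.FP / calls if calls else None


def score_against_truth(
    calls: Sequence, truth: Sequence, pos_tol: int = 10
) -> EvaluationResult:
    """Greedy nearest-first matching of calls to planted insertions.

    A call is a true positive when its left breakpoint lies within
    ``pos_tol`` of a not-yet-matched truth position on the same contig;
    duplicates of a matched truth and unmatched calls are false positives.
    """
    if pos_tol < 0:
        raise ValueError("pos_tol must be non-negative")
    pairs = []
    for i, c in enumerate(calls):
        for j, t in enumerate(truth):
            if c.contig != t.contig:
                continue
            d = min(abs(c.left_bp - t.pos), abs(c.right_bp - t.pos))
            if d <= pos_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_calls: set[int] = set()
    used_truth: set[int] = set()
    for d, i, j in pairs:
        if i in used_calls or j in used_truth:
            continue
        used_calls.add(i)
        used_truth.add(j)
    tp = len(used_truth)
    result = EvaluationResult(TP=tp, FP=len(calls) - tp, FN=len(truth) - tp)
    assert result.TP + result.FP == len(calls)
    assert result.TP + result.FN == len(truth)
    return result


def normalize_calls(n_calls: int, total_reads: int) -> float:
    """Calls per 100 million reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return n_calls * 1e8 / total_reads


def _seq_identity(a: str, b: str) -> float:
    if not a or not b:
        return 1.0 if a == b else 0.0
    n = max(len(a), len(b))
    ed = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - ed / n


@dataclass(slots=True)
class SampleComparison:
    common: list = field(default_factory=list)   # (call_a, call_b) pairs
    unique_a: list = field(default_factory=list)
    unique_b: list = field(default_factory=list)
    norm_a: float | None = None  # unique calls per 100M reads
    norm_b: float | None = None
    fold: float | None = None    # norm_a / norm_b; None when undefined


def diff_samples(
    calls_a: Sequence,
    calls_b: Sequence,
    pos_tol: int = 10,
    min_seq_identity: float = 0.90,
    reads_a: int | None = None,
    reads_b: int | None = None,
) -> SampleComparison:
    """Partition two call sets into common and sample-specific calls.

    Calls match when on the same contig with breakpoints within ``pos_tol``
    and insertion sequences at >= 90% identity.  The fold change is the
    ratio of sample-specific calls normalized per 100 million reads
    (None when either read count is missing or the denominator is zero).
    """
    pairs = []
    for i, ca in enumerate(calls_a):
        for j, cb in enumerate(calls_b):
            if ca.contig != cb.contig:
                continue
            d = abs(ca.left_bp - cb.left_bp)
            if d > pos_tol:
                continue
            if _seq_identity(ca.ins_seq, cb.ins_seq) < min_seq_identity:
                continue
            pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    result = SampleComparison()
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        result.common.append((calls_a[i], calls_b[j]))
    result.unique_a = [c for i, c in enumerate(calls_a) if i not in used_a]
    result.unique_b = [c for j, c in enumerate(calls_b) if j not in used_b]
    assert len(result.common) + len(result.unique_a) == len(calls_a)
    assert len(result.common) + len(result.unique_b) == len(calls_b)
    if reads_a is not None and reads_b is not None:
        result.norm_a = normalize_calls(len(result.unique_a), reads_a)
        result.norm_b = normalize_calls(len(result.unique_b), reads_b)
        if result.norm_b > 0:
            result.fold = result.norm_a / result.norm_b
    return result
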