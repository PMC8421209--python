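"""Variant extraction, template search, event classification, clonality."""

import random

import edlib
import pytest

from mmbti.call import (
    MMBTICall,
    SearchConfig,
    classify_event,
    extract_variant,
    find_template,
    flag_clonality,
    resolve_multi_template,
)
from mmbti.cluster import ConsensusContig
from mmbti.io import revcomp
from mmbti.simulate import make_random_reference


def _contig(seq, left=None, right=None, side="LR"):
    return ConsensusContig(
        seq=seq, side=side, per_column_support=[3] * len(seq),
        left_ref_start=left, right_ref_end=right, n_reads=3,
    )


def _random_ins(ref_seq, pos, length, seed, right_resume=None):
    """Random insertion that cannot be rotated into the flanks."""
    rng = random.Random(seed)
    right_resume = pos if right_resume is None else right_resume
    while True:
        ins = "".join(rng.choices("ACGT", k=length))
        if ins[0] != ref_seq[pos] and ins[-1] != ref_seq[right_resume - 1]:
            return ins


class TestExtractVariant:
    def test_pure_insertion(self, ref50k, ref50k_seq):
        x = _random_ins(ref50k_seq, 1040, 30, seed=0)
        c = _contig(ref50k_seq[980:1040] + x + ref50k_seq[1040:1100], 980, 1100)
        left, right, ins, one_sided = extract_variant(c, ref50k, "sim1")
        assert (left, right, ins, one_sided) == (1040, 1040, x, False)

    def test_replacement_gap(self, ref50k, ref50k_seq):
        x = _random_ins(ref50k_seq, 1040, 30, seed=1, right_resume=1070)
        c = _contig(ref50k_seq[980:1040] + x + ref50k_seq[1070:1130], 980, 1130)
        left, right, ins, _ = extract_variant(c, ref50k, "sim1")
        assert (left, right, ins) == (1040, 1070, x)

    def test_reference_slice_yields_no_call(self, ref50k, ref50k_seq):
        c = _contig(ref50k_seq[980:1100], 980, 1100)
        assert extract_variant(c, ref50k, "sim1") is None

    def test_min_len_discards_short_insertions(self, ref50k, ref50k_seq):
        x = _random_ins(ref50k_seq, 1040, 8, seed=2)
        c = _contig(ref50k_seq[980:1040] + x + ref50k_seq[1040:1100], 980, 1100)
        assert extract_variant(c, ref50k, "sim1", min_len=10) is None
        assert extract_variant(c, ref50k, "sim1", min_len=6) is not None

    def test_one_edge_contig_right_boundary_recovered(self, ref50k, ref50k_seq):
        """An L-only contig with enough downstream flank pins both breakpoints."""
        x = _random_ins(ref50k_seq, 2040, 30, seed=3)
        c = _contig(ref50k_seq[1980:2040] + x + ref50k_seq[2040:2090],
                    left=1980, right=None, side="L")
        left, right, ins, one_sided = extract_variant(c, ref50k, "sim1")
        assert (left, right, ins, one_sided) == (2040, 2040, x, False)

    def test_consensus_error_in_flank_tolerated(self, ref50k, ref50k_seq):
        x = _random_ins(ref50k_seq, 1040, 30, seed=4)
        flank = list(ref50k_seq[980:1040])
        flank[10] = "A" if flank[10] != "A" else "C"  # lone support-1 error
        c = _contig("".join(flank) + x + ref50k_seq[1040:1100], 980, 1100)
        left, right, ins, _ = extract_variant(c, ref50k, "sim1")
        assert (left, right, ins) == (1040, 1040, x)


class TestFindTemplate:
    def _planted_call(self, ref_seq, pos=2080, length=30, offset=80):
        t0 = pos - offset
        ins = revcomp(ref_seq[t0 : t0 + length])
        return MMBTICall("sim1", pos, pos, ins, support=10), t0

    def test_planted_inverted_template_found_exactly(self, ref50k, ref50k_seq):
        call, t0 = self._planted_call(ref50k_seq)
        tm = find_template(call, ref50k, SearchConfig())
        assert tm is not None
        assert tm.orientation == "inverted"
        assert tm.identity == pytest.approx(1.0)
        assert (tm.interval.start, tm.interval.end) == (t0, t0 + 30)
        assert tm.offset_from_insertion == -80
        assert tm.interval.strand == "-"

    def test_absent_template_returns_none(self, ref50k, ref50k_seq):
        cfg = SearchConfig(min_len=15, min_identity=0.9)
        pos = 30_000
        # a seeded random insertion whose window truly lacks a template,
        # confirmed by exhaustive banded alignment of every >=15 bp piece
        # at a looser identity bound than the caller's gate
        rng = random.Random(17)
        for _ in range(50):
            ins = "".join(rng.choices("ACGT", k=30))
            region = ref50k_seq[pos - 100 - 30 : pos + 100 + 30]
            if not self._oracle_hit(ins, region, cfg.min_len, 0.85):
                break
        else:
            pytest.fail("no template-free insertion found")
        call = MMBTICall("sim1", pos, pos, ins, support=10)
        assert find_template(call, ref50k, cfg) is None

    @staticmethod
    def _oracle_hit(ins, region, min_len, min_identity):
        """Exhaustive check: any >=min_len piece of ins (either orientation)
        placed anywhere in the region at >=min_identity edit identity?"""
        for query in (revcomp(ins), ins):
            for i in range(len(query) - min_len + 1):
                for j in range(i + min_len, len(query) + 1):
                    piece = query[i:j]
                    ed = edlib.align(piece, region, mode="HW")["editDistance"]
                    if 1.0 - ed / len(piece) >= min_identity:
                        return True
        return False

    def test_corrupted_template_below_identity_threshold(self, ref50k, ref50k_seq):
        call, t0 = self._planted_call(ref50k_seq, pos=4080, length=32)
        chars = list(call.ins_seq)
        for i in range(0, 32, 4):  # corrupt 25% of bases, evenly spread
            chars[i] = "A" if chars[i] != "A" else "C"
        call.ins_seq = "".join(chars)
        assert find_template(call, ref50k, SearchConfig(min_identity=0.80)) is None


class TestClassification:
    def test_planted_append_event_is_clsc(self, ref50k, ref50k_seq):
        pos = 6080
        ins = revcomp(ref50k_seq[pos - 80 : pos - 50])
        call = MMBTICall("sim1", pos, pos, ins, support=10)
        find_template(call, ref50k, SearchConfig())
        assert classify_event(call, ref50k) == "CLSC"

    def test_replaced_template_interval_is_ipi(self, ref50k, ref50k_seq):
        t0 = 8000
        ins = revcomp(ref50k_seq[t0 : t0 + 30])
        call = MMBTICall("sim1", t0, t0 + 30, ins, support=10)
        find_template(call, ref50k, SearchConfig())
        assert classify_event(call, ref50k) == "IPI"

    def test_three_segment_insertion_is_cm(self, ref50k, ref50k_seq):
        pos = 10_000
        seg1 = revcomp(ref50k_seq[pos - 80 : pos - 60])   # inverted, upstream
        seg2 = ref50k_seq[pos + 30 : pos + 50]            # direct, downstream
        seg3 = revcomp(ref50k_seq[pos - 40 : pos - 20])   # inverted, upstream
        call = MMBTICall("sim1", pos, pos, seg1 + seg2 + seg3, support=10)
        find_template(call, ref50k, SearchConfig())
        assert classify_event(call, ref50k) == "CM"
        assert len(call.templates) >= 2
        orientations = [t.orientation for t in call.templates]
        assert orientations[0] == "inverted" and "direct" in orientations

    def test_multi_template_segmentation_covers_construct(self, ref50k, ref50k_seq):
        pos = 12_000
        seg1 = revcomp(ref50k_seq[pos - 60 : pos - 40])
        seg2 = ref50k_seq[pos + 20 : pos + 40]
        segments = resolve_multi_template(seg1 + seg2, ref50k, "sim1", pos, pos)
        assert len(segments) == 2
        assert segments[0].orientation == "inverted"
        assert segments[1].orientation == "direct"
        # local alignment may extend a boundary by a coincidentally matching base
        assert abs(segments[0].interval.start - (pos - 60)) <= 1
        assert abs(segments[0].interval.end - (pos - 40)) <= 1
        assert abs(segments[1].interval.start - (pos + 20)) <= 1
        assert abs(segments[1].interval.end - (pos + 40)) <= 1

    def test_random_sequence_has_no_qualifying_segments(self, ref50k):
        rng = random.Random(23)
        ins = "".join(rng.choices("ACGT", k=40))
        segments = resolve_multi_template(ins, ref50k, "sim1", 14_000, 14_000)
        covered = sum(t.query_end - t.query_start for t in segments)
        assert covered / len(ins) < 0.9

    def test_no_template_stays_unresolved(self, ref50k):
        call = MMBTICall("sim1", 16_000, 16_000, "ACGTGGCA" * 4, support=10)
        call.templates = []
        # a random-ish sequence: classification falls through
        cls = classify_event(call, ref50k)
        assert cls in ("unresolved", "CM")  # CM only if segmentation covers it


class TestClonality:
    def test_boundary_is_strict(self):
        assert flag_clonality(9, 30) is False   # 0.30 exactly -> clonal
        assert flag_clonality(8, 30) is True    # < 30% -> sub-clonal
        assert flag_clonality(30, 30) is False

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            flag_clonality(5, 0)
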