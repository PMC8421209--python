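"""Junction microhomology and microhomeology counting."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mmbti.call import MMBTICall, SearchConfig, find_template
from mmbti.io import revcomp
from mmbti.junction import (
    JunctionMH,
    count_microhomeology,
    count_microhomology,
    junction_distribution,
    junctions_for_call,
)
from mmbti.simulate import make_random_reference


# --- independent brute-force oracles ---------------------------------------

def oracle_mh(donor, acceptor):
    best = 0
    for m in range(1, min(len(donor), len(acceptor)) + 1):
        if donor[-m:] == acceptor[-m:]:
            best = m
    return best


def oracle_mheo(donor, acceptor):
    """Enumerate every single-interruption configuration explicitly."""
    a, b = donor[::-1], acceptor[::-1]
    mh = oracle_mh(donor, acceptor)

    def lcp(x, y):
        n = 0
        for c1, c2 in zip(x, y):
            if c1 != c2:
                break
            n += 1
        return n

    best = mh
    limit = min(len(a), len(b))
    for j in range(0, limit + 1):
        if a[:j] != b[:j]:
            break  # interruption must follow an uninterrupted matched walk
        options = [
            j + lcp(a[j + 1 :], b[j + 1 :]),  # aligned mismatch at j
            j + lcp(a[j + 1 :], b[j:]),       # 1-bp gap on the donor
            j + lcp(a[j:], b[j + 1 :]),       # 1-bp gap on the acceptor
        ]
        best = max(best, *options)
    if best > mh:
        return best, True
    return mh, False


class TestMicrohomology:
    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [
            ("GGGATC", "TTTATC", 3),
            ("AAAA", "CCCC", 0),
            ("ACGTACGTACGT", "ACGTACGTACGT", 12),
        ],
    )
    def test_known_junctions(self, donor, acceptor, expected):
        assert count_microhomology(donor, acceptor) == expected
        assert oracle_mh(donor, acceptor) == expected

    def test_symmetric_in_arguments(self):
        rng = random.Random(0)
        for _ in range(200):
            d = "".join(rng.choices("ACGT", k=rng.randint(1, 20)))
            a = "".join(rng.choices("ACGT", k=rng.randint(1, 20)))
            assert count_microhomology(d, a) == count_microhomology(a, d)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_microhomology("", "ACGT")


class TestMicrohomeology:
    def test_mismatch_extension(self):
        # right-to-left: ATC match, G/C mismatch, then TA match again
        mheo, interrupted = count_microhomeology("TAGATC", "TACATC")
        assert count_microhomology("TAGATC", "TACATC") == 3
        assert (mheo, interrupted) == (5, True)

    def test_no_gain_keeps_mh(self):
        # mh = 4 (TCGT) and nothing matches beyond the interruption
        donor, acceptor = "AAAATCGT", "CCCCTCGT"
        mh = count_microhomology(donor, acceptor)
        assert mh == 4
        mheo, interrupted = count_microhomeology(donor, acceptor)
        assert mheo == oracle_mheo(donor, acceptor)[0]
        assert not interrupted or mheo > mh

    def test_single_gap_extension(self):
        # donor CATTG vs acceptor CATG: skipping one T aligns CAT again
        donor, acceptor = "ACATTG", "TTCATG"
        expected = oracle_mheo(donor, acceptor)
        assert count_microhomeology(donor, acceptor) == expected

    def test_interruption_at_the_3prime_most_base(self):
        # the junction-adjacent base itself mismatches; matching may still
        # begin beyond it (mh = 0, mheo > 0)
        donor, acceptor = "GGGGAC", "GGGGAT"
        assert count_microhomology(donor, acceptor) == 0
        mheo, interrupted = count_microhomeology(donor, acceptor)
        assert interrupted and mheo >= 4
        assert mheo == oracle_mheo(donor, acceptor)[0]

    def test_monotone_and_matches_oracle_randomized(self):
        rng = random.Random(1)
        for _ in range(2000):
            d = "".join(rng.choices("ACGT", k=rng.randint(1, 25)))
            a = "".join(rng.choices("ACGT", k=rng.randint(1, 25)))
            mh = count_microhomology(d, a)
            mheo, interrupted = count_microhomeology(d, a)
            assert mheo >= mh
            assert (mheo, interrupted) == oracle_mheo(d, a)

    @settings(derandomize=True, max_examples=300)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=30),
        st.text(alphabet="ACGT", min_size=1, max_size=30),
    )
    def test_agrees_with_oracle_property(self, d, a):
        assert count_microhomology(d, a) == oracle_mh(d, a)
        assert count_microhomeology(d, a) == oracle_mheo(d, a)


class TestJunctionDistribution:
    def _call_with(self, mh, mheo):
        c = MMBTICall("c1", 0, 0, "ACGT")
        c.junctions = [JunctionMH(0, mh, mheo, mheo > mh)]
        c.templates = ["placeholder"]
        return c

    def test_uniform_planted_mh(self):
        calls = [self._call_with(3, 3) for _ in range(10)]
        dist = junction_distribution(calls)
        assert dist["mh"] == {3: 10}
        assert dist["mean_mh"] == pytest.approx(3.0)

    def test_empty_call_set(self):
        dist = junction_distribution([])
        assert dist["mh"] == {} and dist["n_excluded"] == 0

    def test_mixture_recovered(self):
        calls = (
            [self._call_with(0, 1) for _ in range(5)]
            + [self._call_with(2, 2) for _ in range(3)]
            + [self._call_with(4, 6) for _ in range(2)]
        )
        dist = junction_distribution(calls)
        assert dist["mh"] == {0: 5, 2: 3, 4: 2}
        assert dist["mheo"] == {1: 5, 2: 3, 6: 2}
        assert dist["mean_mh"] == pytest.approx((0 * 5 + 2 * 3 + 4 * 2) / 10)

    def test_unresolved_calls_counted_separately(self):
        calls = [self._call_with(1, 1), MMBTICall("c1", 0, 0, "ACGT")]
        dist = junction_distribution(calls)
        assert dist["n_excluded"] == 1


class TestPlantedJunctionRecovery:
    @pytest.mark.parametrize("k", list(range(9)))
    def test_planted_microhomology_recovered(self, k):
        """A template annealing site constructed to share exactly k bases
        with the sequence upstream of the breakpoint is reported as mh=k."""
        ref = make_random_reference(20_000, seed=100 + k)
        seq = list(ref["sim1"])
        pos, offset, L = 10_000, 80, 30
        t0, t1 = pos - offset, pos - offset + L
        # entry junction compares ref upstream of pos with revcomp beyond t1:
        # force exactly k matching bases, then a mismatch
        want = revcomp("".join(seq[t1 : t1 + k + 1]))
        for i in range(k):
            seq[pos - k + i] = want[1 + i]
        if seq[pos - k - 1] == want[0]:
            seq[pos - k - 1] = {"A": "C", "C": "G", "G": "T", "T": "A"}[want[0]]
        mutated = "".join(seq)
        ins = revcomp(mutated[t0:t1])
        from mmbti.io import ReferenceGenome

        ref2 = ReferenceGenome({"sim1": mutated})
        call = MMBTICall("sim1", pos, pos, ins, support=10)
        tm = find_template(call, ref2, SearchConfig())
        assert tm is not None and (tm.interval.start, tm.interval.end) == (t0, t1)
        junctions = junctions_for_call(call, ref2)
        assert junctions[0].mh == k
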