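import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itdscan.regions import ReferenceContig
from itdscan.search import (SearchParams, collect_candidates,
                            dp_similarity_search, derive_duplication,
                            placement_mismatch_counts, trim_and_search)
from itdscan.simulate import (build_itd_allele_truth, make_reference,
                              random_insertion)
from itdscan.softclip import ClipSide, SoftClipEvent

BASES = "ACGT"


def brute_force_best(query, target, frac, prefer="leftmost"):
    """Independent oracle: scan every placement, count mismatches directly."""
    tol = math.floor(frac * len(query))
    best = None
    offsets = range(len(target) - len(query) + 1)
    for off in (offsets if prefer == "leftmost" else reversed(offsets)):
        m = sum(
            1
            for a, b in zip(query, target[off: off + len(query)])
            if a != b or a == "N" or b == "N"
        )
        if m <= tol and (best is None or m < best[1]):
            best = (off, m)
    return best


class TestPlacementSearch:
    def test_exact_substring_found(self):
        target = "TTTTACGTACGTACGTTTTT"
        match = dp_similarity_search("ACGTACGTACGT", target)
        assert (match.ref_start, match.mismatches) == (4, 0)

    def test_tolerated_mismatches_reported(self):
        rng = np.random.default_rng(0)
        target = "".join(rng.choice(list(BASES), 300))
        query = list(target[100:120])
        query[3], query[11] = ("A" if query[3] != "A" else "C",
                               "G" if query[11] != "G" else "T")
        query = "".join(query)
        # tolerance floor(0.10 * 20) = 2 admits exactly this placement
        match = dp_similarity_search(query, target)
        oracle = brute_force_best(query, target, 0.10)
        assert (match.ref_start, match.mismatches) == oracle
        assert match.mismatches == 2

    def test_absent_query_returns_none(self):
        assert dp_similarity_search("A" * 20, "C" * 200) is None

    def test_query_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            dp_similarity_search("ACGTACGTA", "A" * 100)

    def test_n_bases_never_match(self):
        counts = placement_mismatch_counts("ANA", "ANA")
        assert counts[0] == 1  # the N-vs-N column still counts as mismatch

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(150):
            tlen = int(rng.integers(30, 400))
            qlen = int(rng.integers(10, min(50, tlen)))
            target = "".join(rng.choice(list(BASES), tlen))
            if rng.random() < 0.5:  # plant a degraded copy
                start = int(rng.integers(0, tlen - qlen + 1))
                query = list(target[start: start + qlen])
                for pos in rng.choice(qlen, size=int(rng.integers(0, 3)),
                                      replace=False):
                    query[pos] = BASES[int(rng.integers(0, 4))]
                query = "".join(query)
            else:
                query = "".join(rng.choice(list(BASES), qlen))
            got = dp_similarity_search(query, target)
            expected = brute_force_best(query, target, 0.10)
            if expected is None:
                assert got is None
            else:
                assert (got.ref_start, got.mismatches) == expected

    @settings(derandomize=True, max_examples=150)
    @given(st.data())
    def test_brute_force_equivalence_property(self, data):
        target = data.draw(st.text(alphabet=BASES, min_size=20, max_size=120))
        qlen = data.draw(st.integers(10, min(40, len(target))))
        start = data.draw(st.integers(0, len(target) - qlen))
        query = target[start: start + qlen]
        got = dp_similarity_search(query, target)
        expected = brute_force_best(query, target, 0.10)
        assert (got.ref_start, got.mismatches) == expected

    def test_monotone_in_mismatch_tolerance(self):
        rng = np.random.default_rng(5)
        target = "".join(rng.choice(list(BASES), 500))
        query = list(target[200:230])
        query[5] = "A" if query[5] != "A" else "C"
        query[20] = "G" if query[20] != "G" else "T"
        query = "".join(query)
        found_at = []
        for frac in (0.0, 0.05, 0.10, 0.20, 0.49):
            params = SearchParams(max_mismatch_frac=frac)
            found_at.append(dp_similarity_search(query, target, params) is not None)
        # once found, raising the tolerance never loses the match
        assert found_at == sorted(found_at)


def clip_events_for(ref, itd, read_len=120):
    """Construct the two canonical junction clip events from the truth allele."""
    allele, truth = build_itd_allele_truth(ref, itd)
    e, s = truth.dup_end, truth.dup_start
    j_lo, j_hi = truth.allele_junction_start, truth.allele_junction_end
    half = read_len // 2
    # read anchored left of the junction: 3' clip at the unit end
    read3 = allele[j_lo - half: j_lo + half]
    ev3 = SoftClipEvent("r3", ClipSide.THREE_PRIME, e, read3[half:],
                        anchor_start=e - half, anchor_end=e)
    # read anchored right of the junction: 5' clip at the unit start
    read5 = allele[j_hi - half: j_hi + half]
    ev5 = SoftClipEvent("r5", ClipSide.FIVE_PRIME, s, read5[:half],
                        anchor_start=s, anchor_end=s + half)
    return ev3, ev5


class TestTrimAndSearch:
    def test_pure_duplication_no_insertion(self, small_ref):
        clip = small_ref.sequence[760:800]  # exact copy of the 40 bp before b
        event = SoftClipEvent("r", ClipSide.THREE_PRIME, 800, clip, 700, 800)
        match, ins = trim_and_search(event, small_ref)
        assert (match.ref_start, match.ref_end, ins) == (760, 800, "")

    def test_insertion_trimmed_from_junction_end(self, small_ref):
        from itdscan.simulate import ITDSpec

        ins = random_insertion(small_ref, 900, 952, 5, seed=9)
        ev3, ev5 = clip_events_for(small_ref, ITDSpec(900, 52, ins), read_len=130)
        for event in (ev3, ev5):
            match, found_ins = trim_and_search(event, small_ref)
            assert found_ins == ins
            cand = derive_duplication(event, match, found_ins)
            assert (cand.dup_start, cand.dup_end) == (900, 952)

    def test_match_beyond_search_window_rejected(self, small_ref):
        params = SearchParams(search_window=50)
        clip = small_ref.sequence[700:730]  # 100 bp upstream of the breakpoint
        event = SoftClipEvent("r", ClipSide.THREE_PRIME, 830, clip, 760, 830)
        assert trim_and_search(event, small_ref, params) is None
        wide = SearchParams(search_window=200)
        match, _ = trim_and_search(event, small_ref, wide)
        assert match.ref_start == 700

    def test_five_prime_mirror_of_three_prime(self, small_ref):
        """A 5'-clip instance and its reverse-complement 3' mirror agree."""
        comp = str.maketrans("ACGT", "TGCA")
        flipped = ReferenceContig("flip", small_ref.sequence.translate(comp)[::-1])
        b, dup = 800, 36
        clip5 = small_ref.sequence[b: b + dup]  # copy of [b, b+dup)
        ev5 = SoftClipEvent("r", ClipSide.FIVE_PRIME, b, clip5, b, b + 90)
        m5, _ = trim_and_search(ev5, small_ref)
        L = len(small_ref)
        ev3 = SoftClipEvent("r", ClipSide.THREE_PRIME, L - b,
                            clip5.translate(comp)[::-1],
                            anchor_start=L - b - 90, anchor_end=L - b)
        m3, _ = trim_and_search(ev3, flipped)
        assert (m3.ref_start, m3.ref_end) == (L - m5.ref_end, L - m5.ref_start)


class TestDeriveDuplication:
    def test_five_prime_unit_runs_breakpoint_to_match_end(self, small_ref):
        b, dup = 820, 30
        clip = small_ref.sequence[b: b + dup]
        event = SoftClipEvent("r", ClipSide.FIVE_PRIME, b, clip, b, b + 80)
        match, ins = trim_and_search(event, small_ref)
        cand = derive_duplication(event, match, ins)
        assert (cand.dup_start, cand.dup_end) == (b, b + dup)
        assert cand.dup_length == dup

    def test_degenerate_unit_rejected(self, small_ref):
        from itdscan.search import DuplicationMatch

        event = SoftClipEvent("r", ClipSide.THREE_PRIME, 800, "A" * 12, 700, 800)
        match = DuplicationMatch(ref_start=798, ref_end=810, mismatches=0,
                                 matched_len=12)
        assert derive_duplication(event, match) is None


class TestCollectCandidates:
    @pytest.mark.parametrize("dup_len", [3, 10, 30, 84, 210])
    @pytest.mark.parametrize("ins_len", [0, 5, 13])
    def test_recovers_simulated_geometry(self, dup_len, ins_len):
        from itdscan.regions import TargetRegion
        from itdscan.simulate import ITDSpec
        from itdscan.softclip import scan_reads

        ref = make_reference(3000, seed=dup_len * 100 + ins_len)
        ins = random_insertion(ref, 1200, 1200 + dup_len, ins_len, seed=1)
        ev3, ev5 = clip_events_for(
            ref, ITDSpec(1200, dup_len, ins), read_len=2 * (dup_len + ins_len + 40)
        )
        groups = {(ev3.breakpoint, ev3.side): [ev3],
                  (ev5.breakpoint, ev5.side): [ev5]}
        cands = collect_candidates(groups, ref)
        assert len(cands) == 1  # both sides merge into one candidate
        cand = cands[0]
        assert (cand.dup_start, cand.dup_end) == (1200, 1200 + dup_len)
        assert cand.insertion_seq == ins
        assert set(cand.source_events) == {"r3", "r5"}

    def test_inclusive_pair_both_retained(self, small_ref):
        from itdscan.simulate import ITDSpec

        outer = clip_events_for(small_ref, ITDSpec(700, 210), read_len=140)
        inner = clip_events_for(small_ref, ITDSpec(760, 84), read_len=140)
        groups = {}
        for ev in (*outer, *inner):
            groups.setdefault((ev.breakpoint, ev.side), []).append(ev)
        cands = collect_candidates(groups, small_ref)
        assert {(c.dup_start, c.dup_end) for c in cands} == {(700, 910),
                                                             (760, 844)}

    def test_overlapping_pair_both_retained(self, small_ref):
        from itdscan.simulate import ITDSpec

        a = clip_events_for(small_ref, ITDSpec(700, 90), read_len=140)
        b = clip_events_for(small_ref, ITDSpec(760, 120), read_len=140)
        groups = {}
        for ev in (*a, *b):
            groups.setdefault((ev.breakpoint, ev.side), []).append(ev)
        cands = collect_candidates(groups, small_ref)
        assert {(c.dup_start, c.dup_end) for c in cands} == {(700, 790),
                                                             (760, 880)}
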