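"""FourWay recursion: merge steps, hybrid threshold, coverage, oracle equivalence."""

import numpy as np
import pytest

import strongmark as sm
from strongmark.build import Interval, expand_and_sort, kmer_set_from_occurrences
from strongmark.fourway import PointerState, fourway_interval, fourway_mark, min_suffix_step
from conftest import str_canonical


def _expanded_from_strings(kmers):
    k = len(kmers[0])
    occ = np.array([sm.encode(str_canonical(s)) for s in kmers], dtype=np.uint64)
    return expand_and_sort(kmer_set_from_occurrences(occ, k))


def _raw_array(kmers):
    """Expanded-array object directly from explicit strings (no rc closure):
    lets merge-step scenarios be staged exactly as drawn."""
    k = len(kmers[0])
    stored = np.array(sorted(sm.encode(s) << 1 for s in kmers), dtype=np.uint64)
    return sm.ExpandedArray(k, stored)


class TestMinSuffixStep:
    """Merge steps of a staged depth-6 interval with 5-character suffixes."""

    PREFIX = "CCCCC"  # shared d-1 = 5 characters

    def make(self):
        kmers = [
            self.PREFIX + "A" + "TATCA",
            self.PREFIX + "C" + "TATAA",
            self.PREFIX + "G" + "TATCA",
            self.PREFIX + "T" + "TATCC",
        ]
        arr = _raw_array(kmers)
        state = PointerState.at_interval(arr, Interval(0, 4), d=6)
        return arr, state

    def test_unique_minimum_advances_without_marking(self):
        arr, state = self.make()
        vec = min_suffix_step(arr, state)
        assert vec.v == 0b0010  # TATAA under the C cursor alone
        assert not vec.is_weak_group()
        assert not arr.marks().any()
        assert not state.active(1)  # C bucket exhausted

    def test_equal_minima_mark_weak_pair(self):
        arr, state = self.make()
        min_suffix_step(arr, state)  # consume TATAA
        vec = min_suffix_step(arr, state)
        assert vec.v == 0b0101  # TATCA under both A and G cursors
        assert vec.is_weak_group()
        marked = sorted(sm.decode(c, 11) for c in arr.codes()[arr.marks()])
        assert marked == [self.PREFIX + "ATATCA", self.PREFIX + "GTATCA"]

    def test_loop_runs_until_single_cursor(self):
        arr, state = self.make()
        steps = 0
        while state.n_active() >= 2:
            min_suffix_step(arr, state)
            steps += 1
        # step 1 consumes the lone minimum under C; step 2 retires the
        # tied A/G cursors together, leaving only T active
        assert steps == 2
        assert int(arr.marks().sum()) == 2


class TestFourwayInterval:
    def test_tiny_intervals_are_noops(self, random_kset):
        arr = expand_and_sort(random_kset(20, 9, seed=0))
        fourway_interval(arr, Interval(0, 0), 1, tau=1)
        fourway_interval(arr, Interval(3, 4), 1, tau=1)
        assert not arr.marks().any()

    def test_last_position_pair_marked(self):
        arr = _expanded_from_strings(["AAGAC", "AAGAT", "CTCGG"])
        fourway_interval(arr, Interval(0, len(arr)), 1, tau=1)
        weak = sm.propagate_orientation(arr)
        assert set(map(int, weak)) == {
            sm.canonical_code(sm.encode("AAGAC"), 5),
            sm.canonical_code(sm.encode("AAGAT"), 5),
        }

    @pytest.mark.parametrize("tau", [1, 2, 24, 30, 100])
    def test_threshold_changes_nothing(self, random_kset, tau):
        kset = random_kset(200, 11, seed=11)
        ref = None
        arr = expand_and_sort(kset)
        fourway_interval(arr, Interval(0, len(arr)), 1, tau=tau)
        weak = set(map(int, sm.propagate_orientation(arr)))
        ref = set(map(int, sm.full_pairwise_mark(kset)))
        assert weak == ref

    def test_invalid_tau_rejected(self, random_kset):
        arr = expand_and_sort(random_kset(10, 9, seed=1))
        with pytest.raises(ValueError):
            fourway_interval(arr, Interval(0, len(arr)), 1, tau=0)


class TestFourwayMark:
    def test_empty_array(self):
        arr = sm.ExpandedArray(9, np.empty(0, dtype=np.uint64))
        fourway_mark(arr)
        assert len(arr) == 0

    def test_second_half_equals_full_recursion(self, random_kset):
        for seed in range(5):
            kset = random_kset(300, 13, seed=seed)
            a1 = expand_and_sort(kset)
            a2 = expand_and_sort(kset)
            fourway_mark(a1, second_half_only=True)
            fourway_mark(a2, second_half_only=False)
            assert np.array_equal(
                sm.propagate_orientation(a1), sm.propagate_orientation(a2)
            )

    @pytest.mark.parametrize("g", [0, 1, 2, 3])
    def test_chunking_invariant(self, random_kset, g):
        kset = random_kset(400, 15, seed=3)
        ref_arr = expand_and_sort(kset)
        fourway_mark(ref_arr, g=0)
        arr = expand_and_sort(kset)
        fourway_mark(arr, g=g)
        assert np.array_equal(arr.stored, ref_arr.stored)

    def test_chunk_execution_order_is_irrelevant(self, random_kset, rng):
        from strongmark._kernels import fourway_chunk

        kset = random_kset(400, 15, seed=4)
        ref = expand_and_sort(kset)
        fourway_mark(ref, g=0)
        arr = expand_and_sort(kset)
        ivs = sm.prefix_chunk_bounds(arr, 2)
        order = rng.permutation(len(ivs))
        view = arr.stored.view(np.int64)
        for i in order:
            fourway_chunk(view, 15, ivs[i].start, ivs[i].end, 30, 15 // 2 + 1)
        assert np.array_equal(arr.stored, ref.stored)

    @pytest.mark.parametrize("k", [8, 9, 13])
    def test_first_half_difference_found_via_rc(self, k):
        """A pair differing only at position 1 is invisible to second-half
        processing directly; its rc pair differs at position k and must be
        caught, then unified by propagation."""
        base = "ACGTACGTACGTA"[:k]
        other = ("T" if base[0] != "T" else "G") + base[1:]
        arr = _expanded_from_strings([base, other])
        fourway_mark(arr, second_half_only=True)
        weak = set(map(int, sm.propagate_orientation(arr)))
        assert weak == {
            sm.encode(str_canonical(base)),
            sm.encode(str_canonical(other)),
        }

    @pytest.mark.parametrize("k", [9, 13, 21])
    def test_middle_position_difference_odd_k(self, k):
        base = ("ACGTTGCAG" * 3)[:k]
        mid = k // 2  # 0-based middle of odd k
        other = base[:mid] + ("A" if base[mid] != "A" else "C") + base[mid + 1 :]
        arr = _expanded_from_strings([base, other])
        fourway_mark(arr, second_half_only=True)
        assert len(sm.propagate_orientation(arr)) == 2

    def test_oracle_equivalence_random_suite(self, random_kset):
        for seed, (k, n) in enumerate([(5, 60), (7, 250), (11, 400), (21, 500), (31, 500)]):
            kset = random_kset(n, k, seed=seed)
            res = sm.run_marking(kset, algorithm="fourway-pairwise")
            assert np.array_equal(res.weak, sm.full_pairwise_mark(kset))
            assert np.array_equal(res.weak, sm.neighborhood_mark(kset))

    def test_all_weak_and_all_strong_extremes(self):
        from strongmark.driver import mark_expanded
        from strongmark.synthetic import SyntheticSpec, gen_all_strong, gen_all_weak

        aw = gen_all_weak(SyntheticSpec(n=1000, k=21, seed=1, mode="all_weak"))
        assert mark_expanded(aw, algorithm="fourway-pairwise").weak_fraction == 1.0
        st = gen_all_strong(SyntheticSpec(n=1000, k=21, seed=2, mode="all_strong"))
        assert mark_expanded(st, algorithm="fourway-pairwise").weak_fraction == 0.0
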