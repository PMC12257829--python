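"""Driver: dispatch, propagation, scheduling, result IO, CLI."""

import json

import numpy as np
import pytest

import strongmark as sm
from strongmark import io as skio
from strongmark.build import expand_and_sort, rc_codes
from strongmark.driver import (
    ChunkSpec,
    CorruptedArrayError,
    WeakResult,
    propagate_orientation,
    schedule_chunks,
)


class TestRunMarking:
    def test_empty_set(self):
        kset = sm.CanonicalKmerSet(9, np.empty(0, dtype=np.uint64))
        res = sm.run_marking(kset)
        assert res.n == 0 and res.weak_fraction == 0.0

    def test_unknown_algorithm_rejected(self, random_kset):
        with pytest.raises(ValueError, match="unknown algorithm"):
            sm.run_marking(random_kset(5, 9, seed=0), algorithm="bogus")

    def test_all_algorithms_identical(self, random_kset):
        kset = random_kset(600, 13, seed=1)
        results = [
            sm.run_marking(kset, algorithm=a)
            for a in ("fourway", "fourway-pairwise", "quarter", "pairwise", "neighborhood")
        ]
        for r in results[1:]:
            assert r == results[0]

    def test_partition_is_exhaustive_and_disjoint(self, random_kset):
        kset = random_kset(500, 11, seed=2)
        res = sm.run_marking(kset)
        merged = np.sort(np.concatenate([res.weak, res.strong]))
        assert np.array_equal(merged, kset.codes)
        assert len(np.intersect1d(res.weak, res.strong)) == 0

    @pytest.mark.parametrize("g", [0, 1, 3])
    @pytest.mark.parametrize("s", [0, 2])
    @pytest.mark.parametrize("threads", [1, 4])
    def test_parameters_never_change_result(self, random_kset, g, s, threads):
        kset = random_kset(800, 15, seed=3)
        ref = sm.run_marking(kset, g=0, s=0, threads=1)
        assert sm.run_marking(kset, g=g, s=s, threads=threads) == ref


class TestPropagation:
    def test_single_orientation_mark_propagates(self):
        arr = expand_and_sort(sm.CanonicalKmerSet(4, np.array([198], dtype=np.uint64)))
        arr.stored[0] |= np.uint64(1)  # mark CGTA only
        weak = propagate_orientation(arr)
        assert list(map(int, weak)) == [198]

    def test_both_orientations_dedup(self):
        arr = expand_and_sort(sm.CanonicalKmerSet(4, np.array([198], dtype=np.uint64)))
        arr.stored |= np.uint64(1)
        assert len(propagate_orientation(arr)) == 1

    def test_missing_rc_is_corruption(self):
        stored = np.array([198 << 1 | 1], dtype=np.uint64)  # TACG marked, CGTA absent
        with pytest.raises(CorruptedArrayError):
            propagate_orientation(sm.ExpandedArray(4, stored))

    def test_matches_oracle_on_random_input(self, random_kset):
        kset = random_kset(400, 11, seed=4)
        arr = expand_and_sort(kset)
        sm.fourway_mark(arr)
        assert np.array_equal(propagate_orientation(arr), sm.full_pairwise_mark(kset))


class TestScheduling:
    def test_g0_single_job(self):
        plan = schedule_chunks(ChunkSpec(0, [(0, sm.Interval(0, 10))]), threads=16)
        assert plan["effective_parallelism"] == 1 and len(plan["jobs"]) == 1

    def test_empty_chunks_do_not_count(self):
        jobs = [(0, sm.Interval(0, 0)), (1, sm.Interval(0, 5)), (2, sm.Interval(5, 9))]
        plan = schedule_chunks(ChunkSpec(1, jobs), threads=16)
        assert len(plan["jobs"]) == 2 and plan["effective_parallelism"] == 2

    def test_threads_capped_by_chunks(self):
        jobs = [(i, sm.Interval(i, i + 1)) for i in range(16)]
        assert schedule_chunks(ChunkSpec(2, jobs), threads=16)["effective_parallelism"] == 16
        assert schedule_chunks(ChunkSpec(2, jobs), threads=4)["effective_parallelism"] == 4


class TestResultIO:
    def test_text_round_trip(self, tmp_path, random_kset):
        res = sm.run_marking(random_kset(120, 9, seed=5))
        path = tmp_path / "res.tsv"
        skio.write_results_text(res, path)
        back = skio.read_results_text(path, 9)
        assert back == res

    def test_text_format_line(self, tmp_path):
        res = WeakResult(4, np.array([198], dtype=np.uint64), np.empty(0, dtype=np.uint64))
        path = tmp_path / "one.tsv"
        skio.write_results_text(res, path)
        assert path.read_text() == "TACG\tweak\n"

    def test_binary_round_trip(self, tmp_path, random_kset):
        arr = expand_and_sort(random_kset(60, 11, seed=6))
        arr.stored[::3] |= np.uint64(1)
        skio.write_array(arr, tmp_path / "a.arr", s=1, chunk_id=2)
        back, meta = skio.read_array(tmp_path / "a.arr")
        assert np.array_equal(back.stored, arr.stored)
        assert back.k == 11 and meta["s"] == 1 and meta["chunk_id"] == 2

    def test_wrong_magic_rejected(self, tmp_path):
        p = tmp_path / "bad.arr"
        p.write_bytes(b"\0" * 16)
        (tmp_path / "bad.arr.json").write_text(json.dumps({"magic": "NOPE", "k": 5, "n": 2}))
        with pytest.raises(skio.FormatError, match="magic"):
            skio.read_array(p)

    def test_missing_sidecar_rejected(self, tmp_path):
        p = tmp_path / "naked.arr"
        p.write_bytes(b"\0" * 8)
        with pytest.raises(skio.FormatError, match="sidecar"):
            skio.read_array(p)


class TestCLI:
    def test_build_mark_stats_pipeline(self, tmp_path, write_fasta):
        from click.testing import CliRunner

        from strongmark.cli import main

        fa = write_fasta({"c1": "ACGTACGTTACGATACGACGTACGTAAT"})
        runner = CliRunner()
        r = runner.invoke(main, ["build", "--fasta", str(fa), "-k", "5", "--out", str(tmp_path / "a.arr")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            ["mark", "--input", str(fa), "-k", "5", "--algorithm", "quarter", "--out", str(tmp_path / "m")],
        )
        assert r.exit_code == 0, r.output
        summary = json.loads((tmp_path / "m.json").read_text())
        assert summary["weak"] + summary["strong"] == summary["n"] > 0
        # marking the prebuilt array gives the same weak count
        r = runner.invoke(main, ["mark", "--input", str(tmp_path / "a.arr"), "--out", str(tmp_path / "m2")])
        assert r.exit_code == 0, r.output
        s2 = json.loads((tmp_path / "m2.json").read_text())
        assert s2["weak"] == summary["weak"]

    def test_synth_command_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from strongmark.cli import main

        runner = CliRunner()
        out = tmp_path / "w.arr"
        r = runner.invoke(
            main, ["synth", "--mode", "all-weak", "-n", "200", "-k", "13", "--seed", "5", "--out", str(out)]
        )
        assert r.exit_code == 0, r.output
        arr, meta = skio.read_array(out)
        assert meta["n"] == 200
        arr.check_invariants()
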