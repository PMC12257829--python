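"""Orchestration: algorithm dispatch, chunk scheduling, and propagation.

The marking kernels only discover a weak pair in the orientation whose
single difference falls in the second half of the sequence; the
reverse-complement pair, whose difference is in the first half, is never
compared directly.  Orientation propagation therefore finishes every run:
a canonical k-mer is weak iff either of its orientations was marked.  It
is exactly this one-sided discovery that lets prefix chunks be processed
independently (marks are slice-local), so the result is bit-identical for
every chunking, input split, thread count and chunk order — and for every
algorithm.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import fourway_chunk, quarter_chunk
from .build import (
    CanonicalKmerSet,
    ExpandedArray,
    Interval,
    canonical_codes,
    chunked_expand,
    prefix_chunk_bounds,
    rc_codes,
)
from .fourway import DEFAULT_TAU
from .oracles import full_pairwise_mark, neighborhood_mark
from .quarter import partition_lengths

__all__ = [
    "ALGORITHMS",
    "ChunkSpec",
    "WeakResult",
    "run_marking",
    "mark_expanded",
    "propagate_orientation",
    "schedule_chunks",
    "default_g",
]

ALGORITHMS = ("fourway", "fourway-pairwise", "quarter", "pairwise", "neighborhood")


class CorruptedArrayError(ValueError):
    """A marked entry's reverse complement is missing: closure violated."""


@dataclass
class ChunkSpec:
    """Prefix length g and the resulting (chunk id, Interval) job list."""

    g: int
    jobs: list  # of (chunk_id, Interval)


@dataclass
class WeakResult:
    """Canonical weak/strong partition of an input k-mer set."""

    k: int
    weak: np.ndarray  # sorted canonical codes, uint64
    strong: np.ndarray

    def __post_init__(self) -> None:
        self.weak = np.asarray(self.weak, dtype=np.uint64)
        self.strong = np.asarray(self.strong, dtype=np.uint64)

    @property
    def n(self) -> int:
        return len(self.weak) + len(self.strong)

    @property
    def weak_fraction(self) -> float:
        return len(self.weak) / self.n if self.n else 0.0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeakResult)
            and self.k == other.k
            and np.array_equal(self.weak, other.weak)
            and np.array_equal(self.strong, other.strong)
        )


def default_g(k: int) -> int:
    """Default chunk prefix: 5 (good thread granularity) capped at floor(k/2)."""
    return min(5, k // 2)


def schedule_chunks(chunks: ChunkSpec, threads: int):
    """Execution plan: every chunk once; disjoint slices make any
    interleaving equivalent.  Effective parallelism is bounded by the
    number of nonempty chunks."""
    if threads < 1:
        raise ValueError("threads must be >= 1")
    nonempty = [(cid, iv) for cid, iv in chunks.jobs if iv.end > iv.start]
    return {"jobs": nonempty, "effective_parallelism": min(threads, len(nonempty))}


def propagate_orientation(arr: ExpandedArray) -> np.ndarray:
    """Canonical weak set from in-band marks: cc of every marked entry.

    The rc of each marked entry is located by binary search; a missing rc
    means the array lost orientation closure and is an error.
    """
    codes = arr.codes()
    marked = arr.marks()
    mcodes = codes[marked]
    if len(mcodes) == 0:
        return np.empty(0, dtype=np.uint64)
    rcs = rc_codes(mcodes, arr.k)
    pos = np.searchsorted(codes, rcs)
    inside = pos < len(codes)
    ok = inside.copy()
    ok[inside] = codes[pos[inside]] == rcs[inside]
    if not np.all(ok):
        raise CorruptedArrayError("marked entry without reverse complement in array")
    return np.unique(np.maximum(mcodes, rcs))


def _algo_params(algorithm: str, tau, k: int):
    if algorithm == "fourway":
        return 1
    if algorithm == "fourway-pairwise":
        return DEFAULT_TAU if tau is None else tau
    return tau  # quarter: unused


def _run_jobs(stored_views, algorithm: str, k: int, tau: int, threads: int, jobs):
    """Execute (array_index, Interval) marking jobs, possibly in parallel.

    Kernels release the GIL, slices are disjoint, and the outcome is
    order-independent, so a thread pool is purely a speed knob.
    """
    if algorithm == "quarter":
        spec = partition_lengths(k)

        def work(job):
            ai, iv = job
            quarter_chunk(stored_views[ai], k, iv.start, iv.end, spec.ell, spec.len_s1, spec.len_s2)

    else:
        start_depth = (k // 2) + 1

        def work(job):
            ai, iv = job
            fourway_chunk(stored_views[ai], k, iv.start, iv.end, tau, start_depth)

    if threads <= 1:
        for job in jobs:
            work(job)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            list(pool.map(work, jobs))


def mark_expanded(
    arr: ExpandedArray,
    algorithm: str = "fourway-pairwise",
    tau: int | None = None,
    g: int | None = None,
    threads: int = 1,
) -> WeakResult:
    """Mark an existing expanded array in place and return the canonical
    weak/strong partition of the canonical k-mers it contains."""
    if algorithm not in ("fourway", "fourway-pairwise", "quarter"):
        raise ValueError(f"algorithm {algorithm!r} cannot run on an expanded array")
    k = arr.k
    g = default_g(k) if g is None else g
    tau = _algo_params(algorithm, tau, k)
    view = arr.stored.view(np.int64)
    jobs = [(0, iv) for iv in prefix_chunk_bounds(arr, g)]
    plan = schedule_chunks(ChunkSpec(g, jobs), threads)
    _run_jobs([view], algorithm, k, tau, plan["effective_parallelism"], plan["jobs"])
    weak = propagate_orientation(arr)
    allc = np.unique(canonical_codes(arr.codes(), k))
    strong = np.setdiff1d(allc, weak, assume_unique=True)
    return WeakResult(k, weak, strong)


def run_marking(
    kset: CanonicalKmerSet,
    algorithm: str = "fourway-pairwise",
    tau: int | None = None,
    g: int | None = None,
    threads: int = 1,
    s: int = 0,
) -> WeakResult:
    """Full pipeline: expand (optionally in 4**s prefix chunks), dispatch
    the selected marking algorithm over 4**g prefix chunks, propagate
    orientations, and return the weak/strong partition of the input set.

    The result is identical for every algorithm and every (tau, g, s,
    threads) combination; only speed and memory profile change.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    k = kset.k
    if algorithm == "pairwise":
        weak = full_pairwise_mark(kset)
    elif algorithm == "neighborhood":
        weak = neighborhood_mark(kset)
    else:
        g = default_g(k) if g is None else g
        tau = _algo_params(algorithm, tau, k)
        arrays = list(chunked_expand(kset, s))
        views = [a.stored.view(np.int64) for a in arrays]
        jobs = []
        for ai, a in enumerate(arrays):
            for iv in prefix_chunk_bounds(a, g):
                jobs.append((ai, iv))
        plan = schedule_chunks(ChunkSpec(g, jobs), threads)
        _run_jobs(views, algorithm, k, tau, plan["effective_parallelism"], plan["jobs"])
        full = ExpandedArray(k, np.concatenate([a.stored for a in arrays]) if arrays else np.empty(0, np.uint64))
        weak = propagate_orientation(full)
    strong = np.setdiff1d(kset.codes, weak, assume_unique=True)
    return WeakResult(k, np.sort(weak), strong)
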