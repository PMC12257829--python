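"""Uniqueness classification and block-wise genomic profiles.

A canonical k-mer of a sequence collection is *strongly unique* if it
occurs once (count 1) and has no canonical Hamming-distance-1 neighbor in
the collection's k-mer set; *weakly unique* if it occurs once but has such
a neighbor; *non-unique* if it occurs at least twice.  Strongly unique
k-mers place a read robustly: no single substitution can turn them into
another k-mer of the collection.

The block profile reports, per fixed-size window of each sequence, the
fraction of valid k-mer start positions falling into each class — a
position-resolved view of where a genome is robustly mappable and where
repeats dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from ._kernels import block_counts_kernel
from .build import CanonicalKmerSet, sequence_to_digits, iter_fasta
from .driver import WeakResult

__all__ = ["UniquenessClass", "Classification", "classify", "block_profile", "DEFAULT_BLOCK_SIZE"]

DEFAULT_BLOCK_SIZE = 100_000


class InconsistencyError(ValueError):
    pass


class UniquenessClass(IntEnum):
    strongly_unique = 0
    weakly_unique = 1
    non_unique = 2


@dataclass
class Classification:
    """Three-way uniqueness partition of a canonical k-mer set."""

    k: int
    codes: np.ndarray  # sorted canonical codes
    labels: np.ndarray  # uint8 UniquenessClass values, aligned with codes

    def label_of(self, code: int) -> UniquenessClass:
        i = int(np.searchsorted(self.codes, np.uint64(code)))
        if i >= len(self.codes) or self.codes[i] != np.uint64(code):
            raise KeyError(f"code {code} not in classification")
        return UniquenessClass(int(self.labels[i]))

    def class_counts(self) -> dict:
        out = {c.name: 0 for c in UniquenessClass}
        vals, cnts = np.unique(self.labels, return_counts=True)
        for v, c in zip(vals, cnts):
            out[UniquenessClass(int(v)).name] = int(c)
        return out


def classify(kset: CanonicalKmerSet, weak: WeakResult) -> Classification:
    """Combine counts and weak marks into the three-way classification.

    count >= 2 dominates (non-unique regardless of weakness); count 1
    splits on membership in the weak set.
    """
    if not np.all(np.isin(weak.weak, kset.codes)):
        raise InconsistencyError("weak set contains codes absent from the k-mer set")
    labels = np.full(len(kset), UniquenessClass.strongly_unique, dtype=np.uint8)
    is_weak = np.isin(kset.codes, weak.weak)
    labels[is_weak] = UniquenessClass.weakly_unique
    labels[kset.counts >= 2] = UniquenessClass.non_unique
    return Classification(kset.k, kset.codes.astype(np.uint64), labels)


def block_profile(
    fasta_path,
    k: int,
    classes: Classification,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """Per-block class fractions of k-mer start positions, per sequence.

    A k-mer starts in the block containing its leftmost base (0-based,
    half-open blocks [i*B, (i+1)*B)).  Windows overlapping a non-ACGT
    character count in neither numerator nor denominator; blocks without
    any valid start get NaN fractions.  Columns are BED-compatible
    0-based half-open coordinates.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rows = []
    codes_view = classes.codes.view(np.int64)
    labels = classes.labels
    for name, seq in iter_fasta(fasta_path):
        vals = sequence_to_digits(seq)
        nblocks = max(1, -(-len(vals) // block_size))
        counts = np.zeros((nblocks, 3), dtype=np.int64)
        nvalid = np.zeros(nblocks, dtype=np.int64)
        if len(vals) >= k:
            status = block_counts_kernel(vals, k, codes_view, labels, block_size, counts, nvalid)
            if status < 0:
                raise InconsistencyError(
                    f"sequence {name!r} contains a k-mer missing from the classification"
                )
        for b in range(nblocks):
            nv = int(nvalid[b])
            fr = counts[b] / nv if nv else np.full(3, np.nan)
            rows.append(
                {
                    "sequence": name,
                    "block_start": b * block_size,
                    "block_end": min((b + 1) * block_size, len(vals)),
                    "n_valid_starts": nv,
                    "frac_strongly_unique": fr[0],
                    "frac_weakly_unique": fr[1],
                    "frac_non_unique": fr[2],
                }
            )
    return pd.DataFrame(rows)


def write_profile_tsv(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)
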