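"""On-disk formats: flat binary code arrays and text weak/strong tables.

Binary array format (``.arr`` by convention): little-endian unsigned
64-bit stored values (``code << 1 | markbit``), sorted; a JSON sidecar at
``<path>.json`` carries ``{"magic": "SKARR1", "k": ..., "s": ...,
"chunk_id": ..., "n": ...}``.  ``s``/``chunk_id`` identify a prefix chunk
of a split build (-1 for an unsplit array).

Text result format (``.tsv``): one canonical k-mer per line,
``<SEQUENCE>\t<weak|strong>``, sorted by code.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import codec
from .build import ExpandedArray

__all__ = ["MAGIC", "write_array", "read_array", "write_results_text", "read_results_text"]

MAGIC = "SKARR1"


class FormatError(ValueError):
    pass


def write_array(arr: ExpandedArray, path, s: int = 0, chunk_id: int = -1) -> None:
    path = Path(path)
    arr.stored.astype("<u8").tofile(path)
    meta = {"magic": MAGIC, "k": arr.k, "s": s, "chunk_id": chunk_id, "n": len(arr)}
    path.with_name(path.name + ".json").write_text(json.dumps(meta) + "\n")


def read_array(path) -> tuple[ExpandedArray, dict]:
    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar header {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("magic") != MAGIC:
        raise FormatError(f"bad magic in {sidecar}: {meta.get('magic')!r}")
    stored = np.fromfile(path, dtype="<u8").astype(np.uint64)
    if len(stored) != meta["n"]:
        raise FormatError(f"entry count mismatch in {path}: {len(stored)} != {meta['n']}")
    return ExpandedArray(meta["k"], stored), meta


def write_results_text(result, path) -> None:
    """Write a WeakResult as '<kmer>\\t<weak|strong>' lines, sorted by code."""
    k = result.k
    rows = [(int(c), "weak") for c in result.weak]
    rows += [(int(c), "strong") for c in result.strong]
    rows.sort()
    with open(path, "w") as fh:
        for code, label in rows:
            fh.write(f"{codec.decode(code, k)}\t{label}\n")


def read_results_text(path, k: int):
    """Read the text format back into a WeakResult (lossless round trip)."""
    from .driver import WeakResult

    weak, strong = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            seq, _, label = line.partition("\t")
            code = codec.encode(seq)
            if label == "weak":
                weak.append(code)
            elif label == "strong":
                strong.append(code)
            else:
                raise FormatError(f"bad label {label!r} in {path}")
    return WeakResult(
        k,
        np.sort(np.array(weak, dtype=np.uint64)),
        np.sort(np.array(strong, dtype=np.uint64)),
    )
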