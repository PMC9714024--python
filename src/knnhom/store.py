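"""Binary per-protein vector store.

One store is a pair of files: ``<path>`` holds a small fixed header followed
by an N x d matrix of little-endian 32-bit floats, and ``<path>.ids`` is a
newline-delimited UTF-8 sidecar with one protein ID per matrix row.  The
header records N, d and a metric hint (which similarity the vectors were
meant to be searched under) so downstream consumers can refuse mismatched
inputs early.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

MAGIC = b"KNNH"
VERSION = 1

_METRIC_CODES = {"cosine": 0, "euclidean": 1}
_METRIC_NAMES = {v: k for k, v in _METRIC_CODES.items()}

_HEADER = struct.Struct("<4sBBQQ")  # magic, version, metric, N, d


def ids_path(path: str | Path) -> Path:
    return Path(str(path) + ".ids")


@dataclass
class EmbeddingStore:
    """In-memory view of a vector store: row-aligned IDs and float32 matrix."""

    ids: list[str]
    vectors: np.ndarray  # (N, d) float32
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (N, d) matrix")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError(
                f"ID count ({len(self.ids)}) does not match row count "
                f"({self.vectors.shape[0]})"
            )
        if self.metric not in _METRIC_CODES:
            raise ValueError(f"unknown metric hint {self.metric!r}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("store contains non-finite values")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        try:
            i = self.ids.index(protein_id)
        except ValueError:
            raise KeyError(protein_id) from None
        return self.vectors[i]


def write_store(path: str | Path, store: EmbeddingStore) -> None:
    path = Path(path)
    n, d = store.vectors.shape
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, VERSION, _METRIC_CODES[store.metric], n, d))
        fh.write(np.ascontiguousarray(store.vectors, dtype="<f4").tobytes())
    ids_path(path).write_text("".join(i + "\n" for i in store.ids), encoding="utf-8")


def read_store(path: str | Path, expect_dim: int | None = None) -> EmbeddingStore:
    """Read a store; ``expect_dim`` lets callers reject dimension mismatches."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER.size:
        raise ValueError(f"{path}: truncated store header")
    magic, version, metric_code, n, d = _HEADER.unpack_from(raw)
    if magic != MAGIC:
        raise ValueError(f"{path}: not a knnhom vector store (bad magic)")
    if version != VERSION:
        raise ValueError(f"{path}: unsupported store version {version}")
    if metric_code not in _METRIC_NAMES:
        raise ValueError(f"{path}: unknown metric code {metric_code}")
    body = raw[_HEADER.size:]
    expected = n * d * 4
    if len(body) != expected:
        raise ValueError(f"{path}: expected {expected} data bytes, found {len(body)}")
    vectors = np.frombuffer(body, dtype="<f4").reshape(n, d).astype(np.float32)
    ids = ids_path(path).read_text(encoding="utf-8").splitlines()
    if len(ids) != n:
        raise ValueError(
            f"{path}: sidecar lists {len(ids)} IDs but store holds {n} rows"
        )
    if expect_dim is not None and d != expect_dim:
        raise ValueError(f"{path}: dimension {d} does not match expected {expect_dim}")
    return EmbeddingStore(ids=ids, vectors=vectors, metric=_METRIC_NAMES[metric_code])
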