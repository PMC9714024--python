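"""Exhaustive and HNSW approximate nearest-neighbor search over protein vectors.

Scores follow a single "higher is better" convention: cosine similarity in
[-1, 1], or negative Euclidean distance.  Exhaustive search scores the whole
database and is exact; the HNSW index trades a small recall loss for
sub-linear query time, with graph quality controlled by M (max links per
node per layer; layer 0 allows 2M), ef_construction (candidate-list size at
build) and ef_search (candidate-list size at query time).

Both index kinds serialize to a vector-store file plus a ``.graph`` sidecar
and rebuild bit-identically from the same seed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _hnsw
from .embedders import ProteinVector
from .store import EmbeddingStore, read_store, write_store

_METRIC_CODES = {"cosine": 0, "euclidean": 1}
_KIND_CODES = {"exhaustive": 0, "hnsw": 1}

_GRAPH_MAGIC = b"KNNG"
_GRAPH_VERSION = 1


@dataclass(frozen=True)
class Neighbor:
    target_id: str
    score: float


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between u and v, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("undefined cosine: zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _as_query(query) -> np.ndarray:
    if isinstance(query, ProteinVector):
        query = query.vector
    q = np.ascontiguousarray(query, dtype=np.float32)
    if q.ndim != 1:
        raise ValueError("query must be a 1-D vector")
    return q


def _prepare(vectors: np.ndarray, metric: str) -> np.ndarray:
    """Float32 scoring matrix; L2-normalized rows for cosine."""
    data = np.ascontiguousarray(vectors, dtype=np.float32)
    if metric == "cosine":
        norms = np.linalg.norm(data.astype(np.float64), axis=1)
        if np.any(norms == 0.0):
            raise ValueError("undefined cosine: zero vector in database")
        data = (data.astype(np.float64) / norms[:, None]).astype(np.float32)
    return data


def _dist_to_score(dists: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        return 1.0 - dists
    return -np.sqrt(np.maximum(dists, 0.0))


class _IndexBase:
    kind: str

    def __init__(self, store: EmbeddingStore, metric: str):
        if metric not in _METRIC_CODES:
            raise ValueError(f"unknown metric {metric!r}")
        if store.n < 1:
            raise ValueError("cannot index an empty database")
        self.metric = metric
        self.ids = list(store.ids)
        self.vectors = np.ascontiguousarray(store.vectors, dtype=np.float32)
        self._id_arr = np.array(self.ids)
        # rank of each row's ID in ascending ID order, for deterministic ties
        order = np.argsort(self._id_arr, kind="stable")
        self._id_rank = np.empty(len(order), dtype=np.int64)
        self._id_rank[order] = np.arange(len(order))

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def _check_query(self, query) -> np.ndarray:
        q = _as_query(query)
        if q.shape[0] != self.dim:
            raise ValueError(
                f"query dimension {q.shape[0]} does not match index dimension {self.dim}"
            )
        if self.metric == "cosine":
            norm = float(np.linalg.norm(q.astype(np.float64)))
            if norm == 0.0:
                raise ValueError("undefined cosine: zero query vector")
            q = (q.astype(np.float64) / norm).astype(np.float32)
        return q


class ExhaustiveIndex(_IndexBase):
    """Exact search: score all N database vectors and sort."""

    kind = "exhaustive"

    def __init__(self, store: EmbeddingStore, metric: str = "cosine"):
        super().__init__(store, metric)
        self._scoring = _prepare(self.vectors, metric).astype(np.float64)

    def search(self, query, k: int, ef_search: int | None = None) -> list[Neighbor]:
        if k < 1:
            raise ValueError("k must be >= 1")
        q = self._check_query(query).astype(np.float64)
        if self.metric == "cosine":
            scores = self._scoring @ q
        else:
            diff = self._scoring - q
            scores = -np.sqrt(np.einsum("ij,ij->i", diff, diff))
        order = np.lexsort((self._id_rank, -scores))[: min(k, self.n)]
        return [Neighbor(self.ids[i], float(scores[i])) for i in order]


class HNSWIndex(_IndexBase):
    """Approximate search over a layered proximity graph."""

    kind = "hnsw"

    def __init__(
        self,
        store: EmbeddingStore,
        metric: str = "cosine",
        M: int = 42,
        ef_construction: int = 200,
        seed: int = 0,
        _graph: tuple | None = None,
    ):
        super().__init__(store, metric)
        if M < 2:
            raise ValueError("M must be >= 2")
        if ef_construction < M:
            raise ValueError("ef_construction must be >= M")
        self.M = int(M)
        self.ef_construction = int(ef_construction)
        self.seed = int(seed)
        self._data = _prepare(self.vectors, metric)
        self._metric_code = _METRIC_CODES[metric]
        if _graph is None:
            rng = np.random.default_rng(self.seed)
            # geometric level draw with normalization 1/ln(M)
            u = rng.random(self.n)
            u[u == 0.0] = np.finfo(float).tiny
            self.levels = np.floor(-np.log(u) / np.log(self.M)).astype(np.int32)
            (
                self._nbr0,
                self._cnt0,
                self._nbru,
                self._cntu,
                self._entry,
                self._top,
            ) = _hnsw.build_graph(
                self._data, self._metric_code, self.levels, self.M, self.ef_construction
            )
        else:
            (
                self.levels,
                self._nbr0,
                self._cnt0,
                self._nbru,
                self._cntu,
                self._entry,
                self._top,
            ) = _graph

    def search(self, query, k: int, ef_search: int = 256) -> list[Neighbor]:
        if k < 1:
            raise ValueError("k must be >= 1")
        if ef_search < 1:
            raise ValueError("ef_search must be >= 1")
        q = self._check_query(query)
        dists, idx = _hnsw.search_graph(
            self._data,
            self._metric_code,
            q,
            int(k),
            int(ef_search),
            self._nbr0,
            self._cnt0,
            self._nbru,
            self._cntu,
            int(self._entry),
            int(self._top),
        )
        scores = _dist_to_score(dists, self.metric)
        hits = [Neighbor(self.ids[i], float(s)) for i, s in zip(idx, scores)]
        hits.sort(key=lambda h: (-h.score, h.target_id))
        return hits


def build_exhaustive(store: EmbeddingStore, metric: str = "cosine") -> ExhaustiveIndex:
    return ExhaustiveIndex(store, metric=metric)


def build_hnsw(
    store: EmbeddingStore,
    metric: str = "cosine",
    M: int = 42,
    ef_construction: int = 200,
    seed: int = 0,
) -> HNSWIndex:
    return HNSWIndex(store, metric=metric, M=M, ef_construction=ef_construction, seed=seed)


# ---------------------------------------------------------------------------
# serialization: <prefix>.store (+ .ids) for vectors, <prefix>.graph for the
# index structure; byte-deterministic given the build seed


def save_index(index: _IndexBase, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_store(
        prefix.with_suffix(prefix.suffix + ".store"),
        EmbeddingStore(ids=index.ids, vectors=index.vectors, metric=index.metric),
    )
    graph_path = prefix.with_suffix(prefix.suffix + ".graph")
    with open(graph_path, "wb") as fh:
        fh.write(_GRAPH_MAGIC)
        fh.write(
            struct.pack(
                "<BBB", _GRAPH_VERSION, _KIND_CODES[index.kind], _METRIC_CODES[index.metric]
            )
        )
        if index.kind == "hnsw":
            idx: HNSWIndex = index  # type: ignore[assignment]
            ulev = idx._nbru.shape[0]
            fh.write(
                struct.pack(
                    "<IIQQQII",
                    idx.M,
                    idx.ef_construction,
                    idx.seed,
                    idx._entry,
                    idx.n,
                    idx._top,
                    ulev,
                )
            )
            for arr in (idx.levels, idx._cnt0, idx._nbr0, idx._cntu, idx._nbru):
                fh.write(np.ascontiguousarray(arr, dtype="<i4").tobytes())


def load_index(prefix: str | Path):
    prefix = Path(prefix)
    store = read_store(prefix.with_suffix(prefix.suffix + ".store"))
    raw = Path(prefix.with_suffix(prefix.suffix + ".graph")).read_bytes()
    if raw[:4] != _GRAPH_MAGIC:
        raise ValueError(f"{prefix}: not a knnhom index graph file")
    version, kind_code, metric_code = struct.unpack_from("<BBB", raw, 4)
    if version != _GRAPH_VERSION:
        raise ValueError(f"unsupported graph version {version}")
    metric = {v: k for k, v in _METRIC_CODES.items()}[metric_code]
    if kind_code == _KIND_CODES["exhaustive"]:
        return ExhaustiveIndex(store, metric=metric)
    off = 7
    m, efc, seed, entry, n, top, ulev = struct.unpack_from("<IIQQQII", raw, off)
    off += struct.calcsize("<IIQQQII")
    if n != store.n:
        raise ValueError("graph/store row count mismatch")

    def take(shape):
        nonlocal off
        count = int(np.prod(shape))
        arr = np.frombuffer(raw, dtype="<i4", count=count, offset=off).reshape(shape)
        off += count * 4
        return np.ascontiguousarray(arr, dtype=np.int32)

    levels = take((n,))
    cnt0 = take((n,))
    nbr0 = take((n, 2 * m))
    cntu = take((ulev, n))
    nbru = take((ulev, n, m))
    return HNSWIndex(
        store,
        metric=metric,
        M=m,
        ef_construction=efc,
        seed=seed,
        _graph=(levels, nbr0, cnt0, nbru, cntu, entry, top),
    )
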