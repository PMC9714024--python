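"""Batch k-nearest-neighbor queries with self-hit exclusion.

Benchmarks search a query set against a database that usually contains the
queries themselves; a query trivially retrieves itself, so accuracy is
always reported "excluding self-hits".  Self-hits are identified by ID
equality (duplicate sequences under different IDs remain legal hits): one
extra neighbor is fetched and the query's own ID removed.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .embedders import ProteinVector
from .hits import Hit, HitList
from .store import EmbeddingStore
from .vector_index import ExhaustiveIndex, HNSWIndex

_SCORE_KIND = {"cosine": "cosine", "euclidean": "neg_distance"}

K_DEFAULT = 300


def query_knn(
    index: ExhaustiveIndex | HNSWIndex,
    queries: EmbeddingStore | Iterable[ProteinVector],
    k: int = K_DEFAULT,
    exclude_self: bool = True,
    ef_search: int = 256,
) -> dict[str, HitList]:
    """Per-query HitLists of up to k neighbors, optionally without self-hits.

    Queries absent from the index are searched normally (nothing to remove).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kind = _SCORE_KIND[index.metric]
    if isinstance(queries, EmbeddingStore):
        pairs = list(zip(queries.ids, queries.vectors))
    else:
        pairs = [(q.protein_id, q.vector) for q in queries]
    out: dict[str, HitList] = {}
    for query_id, vector in pairs:
        fetch = k + 1 if exclude_self else k
        neighbors = index.search(np.asarray(vector), fetch, ef_search=ef_search)
        hits = [
            Hit(nb.target_id, nb.score, kind)
            for nb in neighbors
            if not (exclude_self and nb.target_id == query_id)
        ][:k]
        out[query_id] = HitList(query_id, hits)
    return out
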