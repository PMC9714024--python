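"""Per-residue embeddings, mean pooling and long-protein windowing.

A protein language model assigns every residue a d-dimensional vector; the
mean over the residue axis, vector[j] = (1/L) * sum_i matrix[i, j], gives the
per-protein vector (global average pooling) used as the search key throughout
this package.  Real pLM embeddings enter through the vector-store format (see
:mod:`knnhom.store`); the built-in :class:`CompositionEmbedder` is the
amino-acid-composition baseline, whose pooled vector is simply the residue
frequency profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol

import numpy as np

from .store import EmbeddingStore

#: The 20 canonical amino acids, alphabetical; index = composition dimension.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/rare codes accepted on input but excluded from composition dims.
EXTENDED_AA = "XBZUO"
_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
_VALID = set(CANONICAL_AA) | set(EXTENDED_AA)


@dataclass
class PerResidueEmbedding:
    """L x d float32 matrix of residue embeddings for one protein."""

    protein_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be L x d with L >= 1 and d >= 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")


@dataclass
class ProteinVector:
    """d-dimensional pooled representation of one protein."""

    protein_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float32)
        if self.vector.ndim != 1:
            raise ValueError("vector must be 1-D")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("vector contains non-finite values")


class Embedder(Protocol):
    """Contract for anything that turns sequences into residue embeddings.

    Implementations must be deterministic (same sequence, bit-identical
    output) and produce one row per residue.
    """

    name: str
    dimension: int

    def embed(self, protein_id: str, sequence: str) -> PerResidueEmbedding:
        ...


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence.upper()) - _VALID
    if bad:
        raise ValueError(f"unknown residue code(s): {''.join(sorted(bad))}")


class CompositionEmbedder:
    """Amino-acid-composition baseline embedder.

    Each residue maps to a 20-dim one-hot row over the canonical alphabet
    (ambiguity codes map to the all-zero row, i.e. a discard bucket), so the
    pooled per-protein vector is the residue-frequency profile.  By
    construction it is invariant under any reordering of the sequence, which
    is exactly why composition is a weak homology-search baseline.
    """

    name = "aa-composition"
    dimension = 20

    def embed(self, protein_id: str, sequence: str) -> PerResidueEmbedding:
        _check_sequence(sequence)
        seq = sequence.upper()
        matrix = np.zeros((len(seq), 20), dtype=np.float32)
        for i, aa in enumerate(seq):
            j = _AA_INDEX.get(aa)
            if j is not None:
                matrix[i, j] = 1.0
        return PerResidueEmbedding(protein_id=protein_id, matrix=matrix)


def embed_composition(sequence: str, protein_id: str = "") -> ProteinVector:
    """20-dim residue-frequency vector over the canonical alphabet.

    Frequencies are counts divided by the full sequence length; non-canonical
    residues (X/B/Z/U/O) are counted into a discard bucket outside the 20
    dimensions, so the entries sum to 1 only when every residue is canonical.
    """
    return pool_mean(CompositionEmbedder().embed(protein_id, sequence))


def pool_mean(emb: PerResidueEmbedding) -> ProteinVector:
    """Global average pooling: column means of the residue-embedding matrix.

    Accumulates in float64 before truncating back to float32 so long proteins
    do not lose precision to running float32 sums.
    """
    pooled = emb.matrix.mean(axis=0, dtype=np.float64)
    return ProteinVector(protein_id=emb.protein_id, vector=pooled.astype(np.float32))


def window_slices(
    sequence: str, window: int = 600, stride: int = 300
) -> list[tuple[int, int, str]]:
    """Cut a sequence into overlapping, fully covering slices.

    Returns half-open 0-based ``(start, end, subsequence)`` intervals.  A
    sequence no longer than ``window`` yields one full-length slice.
    Otherwise slices start at multiples of ``stride``; if the regular grid
    does not reach the final residue, one extra right-anchored slice
    ``(L - window, L)`` is appended so the tail is always covered.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 1 <= stride <= window:
        raise ValueError("stride must satisfy 1 <= stride <= window (gaps otherwise)")
    length = len(sequence)
    if length == 0:
        raise ValueError("empty sequence")
    if length <= window:
        return [(0, length, sequence)]
    slices = []
    start = 0
    while start + window <= length:
        slices.append((start, start + window, sequence[start : start + window]))
        start += stride
    if slices[-1][1] < length:
        slices.append((length - window, length, sequence[length - window :]))
    return slices


def embed_records(
    records: Iterable[tuple[str, str]], embedder: Embedder, metric: str = "cosine"
) -> EmbeddingStore:
    """Pool an embedder over ``(id, sequence)`` records into a vector store."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for protein_id, sequence in records:
        ids.append(protein_id)
        rows.append(pool_mean(embedder.embed(protein_id, sequence)).vector)
    if not ids:
        raise ValueError("no records to embed")
    return EmbeddingStore(ids=ids, vectors=np.vstack(rows), metric=metric)
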