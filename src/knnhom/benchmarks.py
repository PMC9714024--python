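"""Benchmark construction and synthetic datasets.

Two benchmark styles mirror the standard constructions for domain-level
homology search:

* CATH-style: single-label families; every member of a family with at least
  two members is a query, the full set is the target database, and a hit is
  correct when it comes from the query's family.
* Pfam-style: multi-label annotations; 20 members are sampled from every
  family with at least 20 members, guaranteeing each query at least 19
  same-family partners in the sampled set (more when multi-domain proteins
  overlap families).

The synthetic generator produces matched embeddings, sequences and
annotations with known family structure so the full search stack is
testable without any external database: family centroids are drawn
uniformly on the unit d-sphere, member embeddings add isotropic Gaussian
noise (sigma relative to the unit-norm centroid), and member sequences are
per-site mutations of a per-family seed sequence.  Decoy sequences
(shuffled or reversed) provide known-incorrect targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .embedders import CANONICAL_AA
from .evaluation import AnnotationMap, write_annotations
from .seqsearch import SequenceRecord, write_fasta
from .store import EmbeddingStore, write_store


@dataclass(frozen=True)
class BenchmarkSpec:
    kind: str = "pfam20_style"  # or "cath20_style"
    per_family_sample: int = 20
    min_family_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pfam20_style", "cath20_style"):
            raise ValueError(f"unknown benchmark kind {self.kind!r}")
        if self.kind == "pfam20_style" and self.per_family_sample > self.min_family_size:
            raise ValueError("per_family_sample must be <= min_family_size")


def select_queries_cath20_style(ann: AnnotationMap) -> list[str]:
    """All members of families with >= 2 members (single-label annotations)."""
    families: dict[str, list[str]] = {}
    for pid in sorted(ann):
        labels = ann[pid]
        if len(labels) != 1:
            raise ValueError(f"single-label annotations required; {pid!r} has {len(labels)}")
        families.setdefault(next(iter(labels)), []).append(pid)
    queries = []
    for fam in sorted(families):
        members = families[fam]
        if len(members) >= 2:
            queries.extend(members)
    return sorted(queries)


def sample_pfam20_style(ann: AnnotationMap, spec: BenchmarkSpec) -> list[str]:
    """Sample per_family_sample members from each family with >= min_family_size
    members; the deduplicated union is the benchmark set.

    Sampling is uniform without replacement and depends only on the
    annotations and spec.seed, so every sampled protein is guaranteed at
    least per_family_sample - 1 same-family partners in the set.
    """
    families: dict[str, list[str]] = {}
    for pid in sorted(ann):
        for label in sorted(ann[pid]):
            families.setdefault(label, []).append(pid)
    rng = np.random.default_rng(spec.seed)
    chosen: set[str] = set()
    for fam in sorted(families):
        members = sorted(families[fam])
        if len(members) < spec.min_family_size:
            continue
        picked = rng.choice(len(members), size=spec.per_family_sample, replace=False)
        chosen.update(members[i] for i in picked)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# synthetic data


@dataclass(frozen=True)
class SyntheticParams:
    n_families: int = 20
    members_per_family: int = 10
    dim: int = 64
    intra_family_sigma: float = 0.05
    seq_length: int = 120
    mutation_rate: float = 0.1
    indel_rate: float = 0.0
    n_multidomain: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2 or self.members_per_family < 2:
            raise ValueError("need >= 2 families with >= 2 members each")
        if self.dim < 2 or self.seq_length < 2:
            raise ValueError("dim and seq_length must be >= 2")
        if self.intra_family_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must be in [0, 1]")


@dataclass
class SyntheticDataset:
    params: SyntheticParams
    store: EmbeddingStore
    records: list[SequenceRecord]
    annotations: dict[str, frozenset[str]]
    centroids: np.ndarray  # (n_families, dim)

    def family_of(self) -> dict[str, str]:
        """Single grouping family per protein (first label, sorted)."""
        return {pid: sorted(labels)[0] for pid, labels in self.annotations.items()}

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.records}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "sequences.fasta")
        write_store(outdir / "embeddings.store", self.store)
        write_annotations(self.annotations, outdir / "annotations.tsv")
        with open(outdir / "params.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self.params), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _mutate(seq: str, rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    aa = CANONICAL_AA
    out = []
    for ch in seq:
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            continue  # deletion
        if rng.random() < rate:
            # substitute uniformly among the 19 alternatives
            choices = aa.replace(ch, "")
            ch = choices[rng.integers(0, len(choices))]
        out.append(ch)
        if indel_rate > 0 and rng.random() < indel_rate / 2:
            out.append(aa[rng.integers(0, len(aa))])  # insertion
    if not out:
        out.append(aa[rng.integers(0, len(aa))])
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(CANONICAL_AA[i] for i in rng.integers(0, len(CANONICAL_AA), size=length))


def generate_synthetic(params: SyntheticParams = SyntheticParams()) -> SyntheticDataset:
    """Family-structured embeddings + matched mutated sequence families.

    Centroids are uniform on the unit sphere; member embeddings are
    centroid + N(0, sigma^2 I) stored as float32.  Each family has one seed
    sequence; members are per-site mutated copies.  With n_multidomain > 0,
    extra proteins concatenate the (mutated) seeds of two families and
    average the two centroids before noise — a simple multi-domain,
    multi-label regime.
    """
    rng = np.random.default_rng(params.seed)
    centroids = rng.normal(size=(params.n_families, params.dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    fam_labels = [f"FAM{f:04d}" for f in range(params.n_families)]
    seeds = [_random_seq(params.seq_length, rng) for _ in range(params.n_families)]

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    records: list[SequenceRecord] = []
    annotations: dict[str, frozenset[str]] = {}

    for f in range(params.n_families):
        for m in range(params.members_per_family):
            pid = f"F{f:04d}_M{m:03d}"
            vec = centroids[f] + rng.normal(scale=params.intra_family_sigma, size=params.dim)
            seq = _mutate(seeds[f], params.mutation_rate, params.indel_rate, rng)
            ids.append(pid)
            vectors.append(vec)
            records.append(SequenceRecord(pid, seq))
            annotations[pid] = frozenset({fam_labels[f]})

    for d in range(params.n_multidomain):
        fa, fb = rng.choice(params.n_families, size=2, replace=False)
        pid = f"MD{d:04d}"
        vec = (centroids[fa] + centroids[fb]) / 2.0 + rng.normal(
            scale=params.intra_family_sigma, size=params.dim
        )
        seq = _mutate(seeds[fa], params.mutation_rate, params.indel_rate, rng) + _mutate(
            seeds[fb], params.mutation_rate, params.indel_rate, rng
        )
        ids.append(pid)
        vectors.append(vec)
        records.append(SequenceRecord(pid, seq))
        annotations[pid] = frozenset({fam_labels[fa], fam_labels[fb]})

    store = EmbeddingStore(
        ids=ids, vectors=np.vstack(vectors).astype(np.float32), metric="cosine"
    )
    return SyntheticDataset(
        params=params,
        store=store,
        records=records,
        annotations=annotations,
        centroids=centroids,
    )


def make_decoys(
    records: list[SequenceRecord],
    mode: str = "shuffle",
    seed: int = 0,
    domain_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> list[SequenceRecord]:
    """Known-incorrect target sequences: per-record shuffles or reversals.

    Decoy IDs are suffixed ``_shuffled`` / ``_reversed`` so they never
    collide with originals.  With ``domain_intervals`` (0-based half-open,
    per protein), shuffling is region-preserving: only residues outside the
    given intervals are permuted (among themselves, in place).
    """
    if mode not in ("shuffle", "reverse"):
        raise ValueError(f"unknown decoy mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        if mode == "reverse":
            out.append(SequenceRecord(rec.id + "_reversed", rec.sequence[::-1]))
            continue
        chars = list(rec.sequence)
        intervals = (domain_intervals or {}).get(rec.id)
        if intervals:
            protected = set()
            for start, end in intervals:
                protected.update(range(start, end))
            free = [i for i in range(len(chars)) if i not in protected]
            perm = rng.permutation(len(free))
            shuffled = [chars[free[p]] for p in perm]
            for pos, ch in zip(free, shuffled):
                chars[pos] = ch
        else:
            chars = [chars[p] for p in rng.permutation(len(chars))]
        out.append(SequenceRecord(rec.id + "_shuffled", "".join(chars)))
    return out
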