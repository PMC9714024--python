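"""Ranked hit lists: the universal search-result container.

A :class:`HitList` holds one query's ranked targets under a single
"higher is better" score, tagged with the score's kind: ``cosine``
(embedding similarity), ``neg_log_evalue`` (sequence-search significance)
or ``neg_distance`` (Euclidean).  Lists are strictly ordered by descending
score with ties broken by ascending target ID, and never contain a
duplicate target.

On disk, hit lists use a native 4-column TSV (query, target, score, kind)
or the 12-column m8 dialect with the score in the bit-score column and
``NA`` placeholders for alignment-specific columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

SCORE_KINDS = ("cosine", "neg_log_evalue", "neg_distance")


@dataclass(frozen=True)
class Hit:
    target_id: str
    score: float
    kind: str = "cosine"

    def __post_init__(self) -> None:
        if self.kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.kind!r}")


def sort_hits(hits: Iterable[Hit]) -> list[Hit]:
    """Descending score, ties by ascending target ID."""
    return sorted(hits, key=lambda h: (-h.score, h.target_id))


@dataclass
class HitList:
    query_id: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sort_hits(self.hits)
        seen = set()
        for h in self.hits:
            if h.target_id in seen:
                raise ValueError(
                    f"duplicate target {h.target_id!r} in hit list for {self.query_id!r}"
                )
            seen.add(h.target_id)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def top(self) -> Hit | None:
        return self.hits[0] if self.hits else None

    def truncated(self, k: int) -> "HitList":
        return HitList(self.query_id, self.hits[:k])


def write_hits(path: str | Path, hitlists: Iterable[HitList]) -> None:
    """Native 4-column TSV: query, target, score, score_kind."""
    with open(path, "w", encoding="utf-8") as fh:
        for hl in hitlists:
            for h in hl.hits:
                fh.write(f"{hl.query_id}\t{h.target_id}\t{h.score!r}\t{h.kind}\n")


def read_hits(path: str | Path) -> dict[str, HitList]:
    """Read the native 4-column format back into per-query HitLists."""
    per_query: dict[str, list[Hit]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, found {len(parts)}")
            q, t, score, kind = parts
            per_query.setdefault(q, []).append(Hit(t, float(score), kind))
    return {q: HitList(q, hits) for q, hits in per_query.items()}


def write_hits_m8(path: str | Path, hitlists: Iterable[HitList]) -> None:
    """m8 dialect with the score in the bit-score column; alignment-specific
    columns carry NA placeholders."""
    na = "\t".join(["NA"] * 9)
    with open(path, "w", encoding="utf-8") as fh:
        for hl in hitlists:
            for h in hl.hits:
                fh.write(f"{hl.query_id}\t{h.target_id}\t{na}\t{h.score:.6g}\n")


def as_dict(hitlists: Iterable[HitList] | Mapping[str, HitList]) -> dict[str, HitList]:
    if isinstance(hitlists, Mapping):
        return dict(hitlists)
    return {hl.query_id: hl for hl in hitlists}
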