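"""Merging sequence-search and embedding-search hits.

Sequence hits carry E-values (lower is better); embedding hits carry cosine
similarities (higher is better).  The combined score puts both on one
"higher is better" scale: sequence hits score -log(E), embedding hits score
their cosine.  Because merged sequence hits are restricted to E < 0.1 and
cosines never exceed 1, every transformed E-value exceeds every cosine, so
reliable sequence hits always outrank embedding hits.

Three merge strategies:

* ``merge_replace`` — top-1 decision: trust the best sequence hit when its
  E-value passes a threshold T, otherwise fall back to the best embedding
  hit (also when the query has no sequence hit at all).
* ``merge_fill_append`` — fill the result list with sequence hits below the
  E-value threshold, append embedding hits, truncate to the list size.
* ``merge_align_then_rank`` — re-align the embedding hits, union them with
  the sequence hits and rank everything by E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .hits import Hit, HitList, as_dict
from .seqsearch import EVALUE_CUTOFF_DEFAULT, SequenceRecord, align_hitlist

EVALUE_FLOOR = 1e-300  # aligners report E=0 for perfect hits; clamp before log


@dataclass(frozen=True)
class CombinedScoreParams:
    """Knobs of the combined score and merges.

    evalue_threshold T gates the top-1 replace merge; fill_threshold gates
    which sequence hits enter the fill-and-append list (it must stay <= 1 so
    -log(E) > 1 >= cosine for every accepted hit); list_size is the merged
    list length.
    """

    evalue_threshold: float = 0.01
    fill_threshold: float = 0.1
    log_base: float = 10.0
    list_size: int = 300

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if not 0 < self.fill_threshold <= 1:
            raise ValueError("fill_threshold must be in (0, 1]")
        if self.log_base not in (10.0, math.e):
            raise ValueError("log_base must be 10 or e")
        if self.list_size < 1:
            raise ValueError("list_size must be >= 1")


@dataclass(frozen=True)
class Top1Decision:
    query_id: str
    target_id: str | None
    score: float
    source: str  # "sequence" | "embedding" | "none"


@dataclass
class MergeReport:
    """Counts written alongside merged hit files."""

    replaced: int = 0
    appended: int = 0
    deduplicated: int = 0
    dropped: int = 0
    extra: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"replaced\t{self.replaced}\n")
            fh.write(f"appended\t{self.appended}\n")
            fh.write(f"deduplicated\t{self.deduplicated}\n")
            fh.write(f"dropped\t{self.dropped}\n")
            for k in sorted(self.extra):
                fh.write(f"{k}\t{self.extra[k]}\n")


def combined_score(
    evalue: float | None = None,
    cosine: float | None = None,
    params: CombinedScoreParams = CombinedScoreParams(),
) -> float:
    """Single higher-is-better score: -log(E) for sequence hits, cosine
    passthrough for embedding-only hits."""
    if evalue is None and cosine is None:
        raise ValueError("at least one of evalue/cosine must be given")
    if evalue is not None:
        e = max(evalue, EVALUE_FLOOR)
        return -math.log(e) / math.log(params.log_base)
    return float(cosine)


def _evalue_of(hit: Hit, params: CombinedScoreParams) -> float:
    if hit.kind != "neg_log_evalue":
        raise ValueError(f"expected neg_log_evalue score, got {hit.kind}")
    return math.pow(params.log_base, -hit.score)


def merge_replace(
    mmseqs_hits: Iterable[HitList] | Mapping[str, HitList],
    knn_hits: Iterable[HitList] | Mapping[str, HitList],
    T: float = 0.01,
    params: CombinedScoreParams = CombinedScoreParams(),
) -> dict[str, Top1Decision]:
    """Per-query top-1 decision: sequence hit if its E <= T, else embedding hit.

    Queries missing from the sequence results (no hit at all) fall back to
    the embedding hit; queries absent from both are recorded as "no hit".
    """
    seq = as_dict(mmseqs_hits)
    knn = as_dict(knn_hits)
    out: dict[str, Top1Decision] = {}
    for query_id in sorted(set(seq) | set(knn)):
        seq_top = seq[query_id].top() if query_id in seq else None
        use_sequence = False
        if seq_top is not None and math.isfinite(T):
            use_sequence = _evalue_of(seq_top, params) <= T
        elif seq_top is not None and T == math.inf:
            use_sequence = True
        if use_sequence:
            out[query_id] = Top1Decision(query_id, seq_top.target_id, seq_top.score, "sequence")
            continue
        knn_top = knn[query_id].top() if query_id in knn else None
        if knn_top is not None:
            out[query_id] = Top1Decision(query_id, knn_top.target_id, knn_top.score, "embedding")
        else:
            out[query_id] = Top1Decision(query_id, None, math.nan, "none")
    return out


def merge_fill_append(
    mmseqs_hits: Iterable[HitList] | Mapping[str, HitList],
    knn_hits: Iterable[HitList] | Mapping[str, HitList],
    params: CombinedScoreParams = CombinedScoreParams(),
) -> tuple[dict[str, HitList], MergeReport]:
    """Fill with sequence hits at E < fill_threshold, append embedding hits.

    Duplicate (query, target) pairs keep the sequence entry (its -log(E)
    score sits on the calibrated side of the combined scale).  Lists are
    truncated to params.list_size.
    """
    seq = as_dict(mmseqs_hits)
    knn = as_dict(knn_hits)
    report = MergeReport()
    out: dict[str, HitList] = {}
    for query_id in sorted(set(seq) | set(knn)):
        merged: list[Hit] = []
        kept_targets: set[str] = set()
        if query_id in seq:
            for h in seq[query_id].hits:
                if _evalue_of(h, params) < params.fill_threshold:
                    merged.append(h)
                    kept_targets.add(h.target_id)
                else:
                    report.dropped += 1
        if query_id in knn:
            for h in knn[query_id].hits:
                if h.target_id in kept_targets:
                    report.deduplicated += 1
                    continue
                merged.append(h)
                report.appended += 1
        out[query_id] = HitList(query_id, merged).truncated(params.list_size)
    return out, report


def merge_align_then_rank(
    mmseqs_hits: Iterable[HitList] | Mapping[str, HitList],
    knn_hits: Iterable[HitList] | Mapping[str, HitList],
    sequences: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
    params: CombinedScoreParams = CombinedScoreParams(),
    evalue_cutoff: float = EVALUE_CUTOFF_DEFAULT,
) -> tuple[dict[str, HitList], MergeReport]:
    """Re-align embedding hits, union with sequence hits, rank by E-value.

    Embedding hits that cannot be aligned under the E-value cutoff are
    dropped.  Duplicate (query, target) pairs keep the lower E-value.
    """
    seq = as_dict(mmseqs_hits)
    knn = as_dict(knn_hits)
    aligned, dropped = align_hitlist(
        knn, sequences, evalue_cutoff=evalue_cutoff, log_base=params.log_base
    )
    report = MergeReport(dropped=dropped)
    out: dict[str, HitList] = {}
    for query_id in sorted(set(seq) | set(aligned)):
        best: dict[str, Hit] = {}
        for source in (seq.get(query_id), aligned.get(query_id)):
            if source is None:
                continue
            for h in source.hits:
                if h.target_id in best:
                    report.deduplicated += 1
                    if h.score > best[h.target_id].score:
                        best[h.target_id] = h
                else:
                    best[h.target_id] = h
        out[query_id] = HitList(query_id, list(best.values())).truncated(params.list_size)
    return out, report
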