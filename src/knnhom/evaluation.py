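"""Homology-search accuracy statistics.

Given per-query search results and family annotations (the ground truth: a
hit is correct when query and target share at least one family label), this
module computes:

* raw top-1 accuracy (micro average): fraction of queries whose best hit is
  correct;
* family-normalized top-1 accuracy (macro average): per-family accuracy
  averaged over families, removing the bias from large families;
* AUC1: per query, the fraction of its true homologs ranked above the first
  false positive — the standard sensitivity measure for ranked homology
  search;
* pooled precision-recall curves over a descending score sweep;
* percentile-bootstrap confidence intervals (500 rounds, 95% by default)
  and 1.96-standard-error intervals;
* the "hypothetical best" union upper bound for any two-method merger;
* per-length-bin summaries (left-closed, right-open bins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .hits import HitList, as_dict

AnnotationMap = Mapping[str, AbstractSet[str]]

BOOTSTRAP_ROUNDS_DEFAULT = 500


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Two-column TSV (protein_id, family label); multi-label rows repeat."""
    raw: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            raw.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in raw.items()}


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(ann):
            for label in sorted(ann[pid]):
                fh.write(f"{pid}\t{label}\n")


def _labels_of(protein_id: str, ann: AnnotationMap) -> AbstractSet[str]:
    try:
        return ann[protein_id]
    except KeyError:
        raise KeyError(f"protein missing from annotation map: {protein_id!r}") from None


def is_correct(query_id: str, target_id: str, ann: AnnotationMap) -> bool:
    """A hit is correct when query and target share >= 1 family label."""
    return bool(_labels_of(query_id, ann) & _labels_of(target_id, ann))


def _target_of(decision) -> str | None:
    return getattr(decision, "target_id", decision)


# ---------------------------------------------------------------------------
# top-1 accuracies


def top1_raw(decisions: Mapping[str, object], ann: AnnotationMap) -> float:
    """Micro average: fraction of queries whose top hit is correct.

    ``decisions`` maps query -> target ID (or a Top1Decision, or None for
    "no hit"; no-hit counts as incorrect).
    """
    if not decisions:
        raise ValueError("no decisions to score")
    correct = 0
    for query_id, decision in decisions.items():
        target_id = _target_of(decision)
        if target_id is not None and is_correct(query_id, target_id, ann):
            correct += 1
    return correct / len(decisions)


def top1_normalized(
    decisions: Mapping[str, object],
    ann: AnnotationMap,
    family_of_query: Mapping[str, str] | None = None,
) -> float:
    """Macro average: mean over families of the per-family top-1 accuracy.

    Each query must belong to exactly one family for grouping; by default
    that is its single annotation label (an error if a query is
    multi-labelled — pass ``family_of_query`` explicitly in that case).
    """
    if not decisions:
        raise ValueError("no decisions to score")
    if family_of_query is None:
        family_of_query = {}
        for query_id in decisions:
            labels = _labels_of(query_id, ann)
            if len(labels) != 1:
                raise ValueError(
                    f"query {query_id!r} has {len(labels)} labels; "
                    "provide an explicit family_of_query mapping"
                )
            family_of_query[query_id] = next(iter(labels))
    per_family: dict[str, list[int]] = {}
    for query_id, decision in decisions.items():
        target_id = _target_of(decision)
        ok = target_id is not None and is_correct(query_id, target_id, ann)
        per_family.setdefault(family_of_query[query_id], []).append(int(ok))
    means = [float(np.mean(v)) for v in per_family.values() if v]
    return float(np.mean(means))


def hypothetical_best(
    decisions_a: Mapping[str, object],
    decisions_b: Mapping[str, object],
    ann: AnnotationMap,
) -> float:
    """Upper bound for any merger: fraction of queries where at least one
    method's top hit is correct."""
    if set(decisions_a) != set(decisions_b):
        raise ValueError("the two methods must cover the same query set")
    correct = 0
    for query_id in decisions_a:
        for decision in (decisions_a[query_id], decisions_b[query_id]):
            target_id = _target_of(decision)
            if target_id is not None and is_correct(query_id, target_id, ann):
                correct += 1
                break
    return correct / len(decisions_a)


# ---------------------------------------------------------------------------
# AUC1


def auc1(
    query_id: str,
    ranked: HitList | Sequence,
    ann: AnnotationMap,
    total_tp: int,
) -> float:
    """Fraction of the query's homologs ranked above the first false positive.

    ``total_tp`` is the query's number of annotated homologs in the target
    database (self excluded).  A list with no false positive scores the
    number of true positives it contains over ``total_tp``.
    """
    if total_tp < 1:
        raise ValueError("total_tp must be >= 1 (exclude such queries upstream)")
    hits = ranked.hits if isinstance(ranked, HitList) else list(ranked)
    found = 0
    for h in hits:
        target_id = getattr(h, "target_id", h)
        if is_correct(query_id, target_id, ann):
            found += 1
        else:
            break
    return min(found / total_tp, 1.0)


def count_homologs(query_id: str, ann: AnnotationMap, target_ids: Iterable[str]) -> int:
    """Number of database entries sharing >= 1 label with the query, self excluded."""
    labels = _labels_of(query_id, ann)
    return sum(
        1
        for t in target_ids
        if t != query_id and t in ann and bool(labels & ann[t])
    )


def auc1_per_query(
    hitlists: Iterable[HitList] | Mapping[str, HitList],
    ann: AnnotationMap,
    target_ids: Sequence[str],
    cap: int | None = None,
) -> tuple[dict[str, float], list[str]]:
    """AUC1 for every query; queries with zero homologs are excluded.

    With ``cap`` set (e.g. 20 for a 20-per-family sampled benchmark), the
    denominator is min(total_tp, cap) so each query's AUC1 runs from 0 to
    cap-of-cap.  Returns (per-query values, excluded query IDs).
    """
    hitlists = as_dict(hitlists)
    values: dict[str, float] = {}
    excluded: list[str] = []
    for query_id in sorted(hitlists):
        total_tp = count_homologs(query_id, ann, target_ids)
        if total_tp == 0:
            excluded.append(query_id)
            continue
        denom = min(total_tp, cap) if cap is not None else total_tp
        values[query_id] = auc1(query_id, hitlists[query_id], ann, denom)
    return values, excluded


# ---------------------------------------------------------------------------
# precision-recall


def precision_recall(
    hitlists: Iterable[HitList] | Mapping[str, HitList],
    ann: AnnotationMap,
    total_tp: int,
    allow_mixed_kinds: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled precision-recall over a descending global score sweep.

    All hits are pooled and swept from the highest score down; at each hit,
    precision = TP/(TP+FP) and recall = TP/total_tp, with total_tp the sum
    of per-query homolog counts.  Scores must be comparable across queries
    (one score kind, or the combined scale with ``allow_mixed_kinds``).
    """
    hitlists = as_dict(hitlists)
    pooled = []
    kinds = set()
    for query_id in sorted(hitlists):
        for h in hitlists[query_id].hits:
            kinds.add(h.kind)
            pooled.append((h.score, query_id, h.target_id))
    if not pooled:
        raise ValueError("no hits to sweep")
    if len(kinds) > 1 and not allow_mixed_kinds:
        raise ValueError(f"mixed score kinds {sorted(kinds)}; scores are not comparable")
    if total_tp < 1:
        raise ValueError("total_tp must be >= 1")
    pooled.sort(key=lambda x: (-x[0], x[1], x[2]))
    tp = 0
    precision = np.empty(len(pooled))
    recall = np.empty(len(pooled))
    for i, (_, query_id, target_id) in enumerate(pooled):
        if is_correct(query_id, target_id, ann):
            tp += 1
        precision[i] = tp / (i + 1)
        recall[i] = tp / total_tp
    return precision, recall


# ---------------------------------------------------------------------------
# uncertainty


@dataclass(frozen=True)
class Interval:
    mean: float
    lo: float
    hi: float

    @property
    def half_width(self) -> float:
        return (self.hi - self.lo) / 2.0


def bootstrap_ci(
    per_query_values: Sequence[float],
    rounds: int = BOOTSTRAP_ROUNDS_DEFAULT,
    level: float = 0.95,
    seed: int = 0,
) -> Interval:
    """Percentile bootstrap of the mean over queries resampled with replacement."""
    values = np.asarray(per_query_values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty input")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(rounds, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return Interval(float(values.mean()), float(lo), float(hi))


def se_interval(values: Sequence[float], z: float = 1.96) -> Interval:
    """mean +/- z standard errors (z = 1.96 for a 95% interval)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need >= 2 values for a standard error")
    se = arr.std(ddof=1) / math.sqrt(arr.size)
    m = float(arr.mean())
    return Interval(m, m - z * se, m + z * se)


# ---------------------------------------------------------------------------
# length binning


@dataclass(frozen=True)
class BinSummary:
    lo: float
    hi: float
    n: int
    interval: Interval


def length_binned(
    values: Mapping[str, float],
    lengths: Mapping[str, int],
    edges: Sequence[float],
    rounds: int = BOOTSTRAP_ROUNDS_DEFAULT,
    seed: int = 0,
) -> list[BinSummary]:
    """Per-bin means with bootstrap CIs; bins are [lo, hi) and empty bins
    are omitted."""
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("edges must be strictly increasing, length >= 2")
    bins: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for query_id in sorted(values):
        if query_id not in lengths:
            raise KeyError(f"length missing for query {query_id!r}")
        length = lengths[query_id]
        for b in range(len(edges) - 1):
            if edges[b] <= length < edges[b + 1]:
                bins[b].append(values[query_id])
                break
    out = []
    for b, content in enumerate(bins):
        if not content:
            continue
        if len(content) >= 2:
            iv = bootstrap_ci(content, rounds=rounds, seed=seed)
        else:
            iv = Interval(content[0], content[0], content[0])
        out.append(BinSummary(edges[b], edges[b + 1], len(content), iv))
    return out


# ---------------------------------------------------------------------------
# score correlation utility


def score_correlations(
    cosine_scores: Sequence[float], log_evalues: Sequence[float]
) -> tuple[float, float]:
    """(Pearson, Spearman) correlation between paired cosine similarities and
    log-transformed E-values."""
    a = np.asarray(cosine_scores, dtype=np.float64)
    b = np.asarray(log_evalues, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length arrays of >= 2 values")
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    return pearson, spearman


# ---------------------------------------------------------------------------
# report serialization


def write_per_query(path: str | Path, values: Mapping[str, float], column: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"query_id\t{column}\n")
        for query_id in sorted(values):
            fh.write(f"{query_id}\t{values[query_id]!r}\n")


def write_summary(path: str | Path, entries: Mapping[str, object]) -> None:
    """Key-value summary, one ``key<TAB>value`` pair per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in entries:
            fh.write(f"{key}\t{entries[key]}\n")


def write_pr_curve(path: str | Path, precision: np.ndarray, recall: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("recall\tprecision\n")
        for r, p in zip(recall, precision):
            fh.write(f"{r!r}\t{p!r}\n")
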