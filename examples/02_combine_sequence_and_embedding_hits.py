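"""Merge sequence-search E-value hits with embedding k-nn hits.

Uses a noisy synthetic dataset where embedding search alone struggles, so
the benefit of falling back on reliable sequence hits is visible.  Sequence
hits come from the built-in Smith-Waterman aligner scored with
Karlin-Altschul E-values (in real use, import an MMseqs2/BLAST m8 file with
``parse_m8`` + ``hitlists_from_m8`` instead).
"""

from knnhom import (
    Hit,
    HitList,
    SyntheticParams,
    align_hitlist,
    build_exhaustive,
    generate_synthetic,
    hypothetical_best,
    merge_fill_append,
    merge_replace,
    query_knn,
    top1_raw,
)
from knnhom.seqsearch import sequence_db

dataset = generate_synthetic(
    SyntheticParams(intra_family_sigma=0.3, mutation_rate=0.35, seed=11)
)
ann = dataset.annotations

# embedding route: exhaustive cosine k-nn
knn_hits = query_knn(build_exhaustive(dataset.store), dataset.store, k=30)

# sequence route: align every pair, keep E <= 10,000, rank by E-value
db = sequence_db(dataset.records)
all_pairs = {
    q: HitList(q, [Hit(t, 0.0, "cosine") for t in dataset.store.ids if t != q])
    for q in dataset.store.ids
}
seq_hits, _ = align_hitlist(all_pairs, db)
seq_hits = {q: hl.truncated(30) for q, hl in seq_hits.items()}

def top1(hitlists):
    return {q: (hl.hits[0].target_id if hl.hits else None) for q, hl in hitlists.items()}

print(f"embedding-only top-1: {top1_raw(top1(knn_hits), ann):.3f}")
print(f"sequence-only  top-1: {top1_raw(top1(seq_hits), ann):.3f}")

# replace merge: trust sequence hits at E <= T, else use the embedding hit
decisions = merge_replace(seq_hits, knn_hits, T=0.01)
print(f"combined (replace, T=0.01) top-1: {top1_raw(decisions, ann):.3f}")

# upper bound for any merger: a hypothetical oracle picking the correct
# method per query
best = hypothetical_best(top1(seq_hits), top1(knn_hits), ann)
print(f"hypothetical best of both: {best:.3f}")

# fill-and-append merge: sequence hits below E=0.1 first, then cosine hits
merged, report = merge_fill_append(seq_hits, knn_hits)
print(f"fill-append: appended {report.appended} embedding hits, "
      f"{report.deduplicated} duplicates resolved, {report.dropped} weak sequence hits dropped")
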