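"""Pool per-residue embeddings, slice long proteins, and build decoy sets.

Shows the embedder-side utilities: mean pooling of an L x d residue-embedding
matrix, the amino-acid-composition baseline, overlapping 600-residue windows
for long proteins, and shuffled/reversed decoy sequences for benchmarking.
"""

import numpy as np

from knnhom import (
    PerResidueEmbedding,
    SequenceRecord,
    embed_composition,
    make_decoys,
    pool_mean,
    window_slices,
)

# mean pooling: any external embedder's L x d matrix becomes one d-vector
rng = np.random.default_rng(0)
residue_matrix = rng.normal(size=(350, 1024)).astype(np.float32)
vec = pool_mean(PerResidueEmbedding("P12345", residue_matrix))
print(f"pooled {residue_matrix.shape} residue embeddings -> {vec.vector.shape} per-protein vector")

# the composition baseline: a 20-dim residue-frequency profile
seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"
comp = embed_composition(seq)
print(f"composition vector sums to {comp.vector.sum():.3f} over 20 canonical dims")

# order-invariance is exactly why composition is a weak baseline:
shuffled = "".join(rng.permutation(list(seq)))
assert np.array_equal(comp.vector, embed_composition(shuffled).vector)
print("composition is identical for the shuffled sequence (order-blind baseline)")

# long proteins: overlapping 600-residue slices, right-anchored final slice
long_protein = "A" * 1250
slices = window_slices(long_protein, window=600, stride=300)
print(f"1250-residue protein -> slices: {[(s, e) for s, e, _ in slices]}")

# decoys: same composition, destroyed order/direction -> known-wrong targets
records = [SequenceRecord("orig", seq)]
shuf = make_decoys(records, mode="shuffle", seed=1)[0]
rev = make_decoys(records, mode="reverse")[0]
print(f"decoys: {shuf.id} (same composition), {rev.id} (= sequence reversed)")
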