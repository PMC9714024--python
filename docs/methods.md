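# Methods

## Per-protein representations

A protein of length L is represented by the mean of its per-residue
embedding matrix: `v_j = (1/L) Σ_i m_ij` (global average pooling). Pooling
accumulates in float64 and truncates to float32, matching the precision of
pLM output while avoiding running-sum error on long proteins. The package
never runs a language model itself; embeddings enter through the store
format (little-endian float32 N×d matrix with a 22-byte header recording
N, d and a metric hint, plus a newline-delimited UTF-8 ID sidecar). The
reader rejects dimension mismatches and non-finite values at load time.

Two built-in embedders exist for testing and baselines:

* **Amino-acid composition** — each residue is a one-hot 20-dim row over
  the canonical alphabet (alphabetical order), so the pooled vector is the
  residue-frequency profile. Ambiguity codes (X/B/Z/U/O) map to the all-zero
  row: they count toward L but toward no dimension, so frequencies sum to
  < 1 when present. We chose exclusion over redistribution because it is
  transparent and keeps the 20 dimensions interpretable. Composition is
  order-blind by construction — a property the tests exploit — which is why
  it is a floor, not a method.
* **Windowing** — proteins longer than the 600-residue window are cut into
  slices starting at multiples of the stride (default 300, i.e. 50%
  overlap), with one extra right-anchored slice `(L-600, L)` whenever the
  regular grid would miss the tail. Slices are embedded as independent
  sequences; no cross-slice context is attempted.

## Vector search

Scores follow one convention — higher is better: cosine similarity in
[−1, 1], or negative Euclidean distance. Ties break by ascending target ID
so results are identical across platforms.

**Exhaustive search** scores all N database vectors in float64 (cosine via
pre-normalized rows) and sorts. It is the package's internal oracle: the
approximate index is always validated against it, never the other way
round.

**HNSW** follows the original hierarchical-navigable-small-world
construction: node levels drawn geometrically with normalization 1/ln(M);
greedy descent from the top layer; at each insertion layer a best-first
search with an ef_construction-sized candidate list; neighbors chosen by
the select-neighbors heuristic (keep a candidate only if it is closer to
the new node than to every already-selected neighbor); at most M links per
node per layer, 2M on layer 0, with over-full lists re-pruned by the same
heuristic. Defaults: M=42, ef_construction=200 (a common published default;
the index exposes it), ef_search=256. All heap orderings are lexicographic
on (distance, node index) and the only randomness is the seeded level draw,
so builds are bit-deterministic and serialize reproducibly (store file +
versioned graph file). For cosine, database vectors are L2-normalized at
insertion; originals are retained for Euclidean use and serialization.

At 10,000 random 64-dim Gaussian vectors (a deliberately structureless,
hard case), recall@10 versus exhaustive search is ≥ 0.95 at ef_search=256
and increases monotonically in ef_search — the property the test suite
asserts.

## Sequence side

**Smith–Waterman** uses the Gotoh three-matrix recurrence (H/E/F) with
affine gaps, BLOSUM62, gap open 11 / extend 1. Gap convention: a gap of
length g costs `open + (g−1)·extend` — the first gapped residue pays the
open penalty — so setting open = extend recovers plain linear gap costs,
which is how the implementation is cross-checked against an independent
quadratic DP oracle. Traceback runs a three-state machine over stored
pointer matrices; identity is identical pairs over aligned (non-gap) pairs.
A linear-memory score-only kernel handles bulk re-scoring. Both kernels are
numba-compiled.

**E-values** use Karlin–Altschul statistics with fixed gapped constants
λ=0.267, K=0.041 (the standard BLOSUM62 11/1 values):
`bit = (λS − ln K)/ln 2`, `E = m·n·2^(−bit)` with m the query length and n
the total residues of the target set. Equivalence with MMseqs2's E-values
is not claimed — only rank-order compatibility; real search results can be
imported as m8 files and used unchanged. E = 0 from external aligners is
clamped to 1e-300 before log transforms.

Coordinates are 1-based inclusive in m8 files (format convention) and
0-based half-open internally; conversion happens only in the I/O layer.

## Combined scoring and merges

Sequence hits score −log(E) (base 10 by default; base e is supported and
either base preserves the ordering claim), embedding hits their cosine.
Restricting merged sequence hits to E < 0.1 makes every transformed E-value
exceed 1 and hence every cosine, so the two score families never interleave.

* **replace** (top-1): take the best sequence hit if its E ≤ T (default
  0.01), else the best embedding hit; queries without sequence hits fall
  back to embedding hits. T=∞ degenerates to pure sequence search, T=0 to
  pure embedding search. The rule is scoped to the top-1 decision — the
  benchmark it serves — not to deeper ranks.
* **fill-append**: sequence hits with E below the fill threshold (0.1),
  ranked by ascending E, then embedding hits ranked by cosine, truncated to
  the list size (300). Duplicate (query, target) pairs keep the sequence
  entry, whose score sits on the calibrated side of the scale.
* **align-then-rank**: embedding hits are re-aligned (cutoff E ≤ 10,000);
  unalignable hits are dropped and counted; the union with sequence hits is
  ranked by ascending E. Duplicates keep the lower E-value.

All merges are deterministic and idempotent; each emits a report counting
replaced/appended/deduplicated/dropped hits.

## Evaluation

A hit is correct when query and target share ≥ 1 family label; self-hits
are excluded by ID (duplicate sequences under different IDs remain legal
hits). Raw top-1 is the fraction of queries with a correct best hit ("no
hit" counts as wrong); normalized top-1 averages per-family accuracies and
is only defined for single-label groupings (for multi-label data an
explicit query→family map must be supplied). AUC1 is the fraction of a
query's annotated homologs ranked strictly above the first false positive;
its denominator is the query's total homolog count in the database, with an
optional capped variant (denominator min(total, cap), e.g. cap=20 for
20-per-family sampled benchmarks where "x of 20" is the conventional
scale) — both are available because sampled benchmarks are ambiguous on
this point. Queries with zero homologs are excluded with a warning count;
queries with zero hits contribute AUC1 = 0.

Uncertainty: percentile bootstrap over queries (500 rounds, 95% by default,
seeded; BCa was not needed at these sample sizes) and a 1.96·SE normal
interval. Bootstrap coverage is verified by simulation in the test suite
(Bernoulli(0.7), n=400: empirical coverage within [0.92, 0.975]). Length
bins are left-closed right-open; empty bins are omitted.

## Synthetic data

The generator emulates the one property embedding search depends on —
family-structured clusters cohesive under cosine — without modeling pLM
geometry (anisotropy, length effects, domain composition). Family centroids
are uniform on the unit d-sphere; members add isotropic N(0, σ²I) noise, so
σ is directly interpretable relative to the unit-norm centroid. Matched
sequences: one random seed sequence per family, members mutated per-site
uniformly over the 19 alternative residues; indels are off by default so
the sequence and embedding family structures stay aligned (an indel rate is
exposed). A multi-domain mode concatenates two families' seeds and averages
their centroids, giving multi-label proteins; its parameters are exposed
but no quantitative claims are attached. Decoys are full-sequence shuffles
(or region-preserving shuffles given domain intervals) and reversals, with
suffixed IDs.

Defaults — 20 families × 10 members, d=64, σ=0.05, 120-residue sequences,
10% per-site mutation — give ~80% within-family identity and cleanly
separable clusters: every method scores near 1.0, which validates the
machinery rather than discriminating between methods. The acceptance study
therefore also runs a hard regime (σ=0.3, 45% mutation, ~30% within-family
identity) where embedding-only search collapses while alignment holds,
exercising the combined rules in the direction they were designed for.
Passing on synthetic data shows the pipeline's contracts hold, not that
real pLM embeddings have any particular accuracy.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 200-
protein benchmarks for the end-to-end study, 10,000 vectors for HNSW
quality, ~40,000 pairwise alignments of 120-mers for the all-against-all
sequence search, 1,000 simulation replicates for bootstrap calibration.
These sizes make every number recomputable from scratch in seconds to a
couple of minutes on one CPU.

## Known limitations

* The aligner is a plain Gotoh implementation — no k-mer prefilter, no
  banding or SIMD, no profiles/HMMs; it is meant for re-scoring candidate
  lists, not database search.
* Karlin–Altschul constants are fixed, not estimated per scoring system;
  E-values are comparable within a run, not to other tools'.
* HNSW has no delete/update, no product quantization, no sharding.
* The composition embedder is a baseline, not a usable search method.
* Normalized (macro) top-1 is undefined for multi-label annotations without
  an explicit grouping.
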