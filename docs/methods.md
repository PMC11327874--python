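# Methods

## Problem and model

`seqpart` assigns sequences to cross-validation folds such that no pair of
sequences in different folds has k-mer distance below a threshold ε. The
model of similarity is purely compositional: a sequence is its set of
length-k substrings (k-mers), and two sequences are similar to the extent
their sets overlap. This is an alignment-free surrogate for pairwise
identity — fast enough for an all-vs-all comparison of large datasets and
insensitive to rearrangements, at the cost of ignoring positional
information.

The guarantee is enforced structurally, not heuristically: single-linkage
clustering of the sub-ε pair graph puts every sub-ε pair inside one
cluster (transitively — two sequences can share a cluster while being
farther than ε apart, chained through intermediates), and the balancing
step only ever moves whole clusters between folds. The final self-audit
recomputes cross-fold sub-ε pair counts and is asserted to be 0 in the
test suite for every non-inverted, non-Hobohm run.

## Distances

Let A, B be the two key sets, S = |A ∩ B|. The five measures are listed in
the README; all are 0 for identical sets and 1 for disjoint sets. Notes:

- **Mash** maps the Jaccard index J through
  d = −(1/k)·ln(2J/(1+J)), a per-site mutation-rate estimate under a
  Poisson substitution model; it is capped at 1 and defined as 1 when
  J = 0. It compresses distances heavily (at k = 16, J = 0.2 gives
  d ≈ 0.07), so ε values tuned for the set-overlap measures are not
  transferable to Mash.
- **Inverse k-mer coverage**: we could not locate a published formula for
  this measure; the implementation uses the mean-of-cardinalities
  denominator d = 1 − S/((|A|+|B|)/2), clamped to [0, 1], and documents it
  as a placeholder. It should not be treated as a faithful reproduction of
  any external tool's definition.
- Under MinHash, overlaps are estimated within the bottom-s sketch of the
  *union* of the two key sets (the standard merged-sketch estimator);
  under that estimator all five formulas operate on estimated counts.
- Empty sketch versus anything is defined as distance 1.0 with a logged
  warning: no k-mer evidence of similarity is treated as unrelated rather
  than failing the run.
- Edge retention is strictly d < ε. A pair at exactly ε is allowed to be
  separated, since ε is defined as the minimum distance two sequences must
  have to be placed in different folds.

## Sketching

- Hashing is a keyed 64-bit hash (blake2b with an 8-byte digest), seeded
  by `hash_seed` (default 42). It is stable across processes and
  platforms; Python's process-randomized `hash()` is deliberately not
  used anywhere.
- Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
  complement) are the default for nucleotides, making every measure
  strand-invariant; the property is asserted for all five measures in the
  tests. Amino-acid input has no complement and must not use canonical
  mode.
- Windows containing an ambiguity symbol (N/X) are skipped entirely
  rather than expanded — no sequence is invented.
- MinHash is a bottom-s sketch under a single hash function (not s
  independent functions). With s = 1000 the Jaccard estimate has standard
  error ≈ √(J(1−J)/1000) ≤ 0.016, which is why the fidelity check
  (|Ĵ − J| ≤ 0.05 on ≥ 95% of homologous pairs) holds with a wide margin.
- Minimizers keep, for each window of `window` consecutive valid k-mers,
  the k-mer of minimum hash, ties broken by leftmost position for
  determinism. A sequence with fewer k-mers than one window keeps its
  overall minimum. We interpret the window parameter as a length in
  k-mers.
- Default schemes: nucleotide MinHash k=19/s=4096, minimizer k=18/w=16,
  prefix k=16 with a single-base prefix, full mode k=16; amino acids are
  Mash/MinHash-only with k=9. These mirror common practice for
  bacterial-scale comparisons; every value is a flag.

## Clustering

DBSCAN with a minimum neighborhood of one point is exactly single
linkage, so the implementation is a union-find over the edge list
(O(E·α(N)), provably the same partition); correctness is checked against
SciPy's connected components on random graphs. Cluster IDs are assigned
by smallest member input index for reproducible output.

Hobohm 1 pre-clustering processes sequences longest-first (classic
choice, exposed as a flag) and absorbs each sequence into the first
earlier representative within the threshold. Absorption can introduce
cross-fold similarity — an absorbed member is only guaranteed to be
within the threshold of its own representative — so the separation
invariant is *not* asserted when Hobohm is enabled; the tests instead
assert the absorption property itself.

## Fold balancing

"Balance" is formalized as max − min over folds (of weighted load, of
cluster count, or summed per label), which is zero exactly at perfect
balance. The alternative Σ|load − mean| was considered and rejected as an
objective because max − min is the standard makespan-spread criterion and
is what "minimizing the difference between partitions" measures directly.

- **LPT seeding**: clusters in decreasing weight to the least-loaded
  fold, ties to the lowest fold index. The classical (4/3 − 1/(3P))
  approximation guarantee on the max load is verified against brute-force
  enumeration in the tests.
- **Exchange neighborhood**: swaps of one cluster from each fold *plus*
  one-sided moves, modeled as swapping with a zero-weight virtual
  cluster. Pure swaps preserve per-fold cluster counts and cannot fix
  count imbalance; `--swaps-only` restores the strict pair-swap
  neighborhood.
- **Single-pass search**: folds keep their clusters sorted by weight.
  For the weight-spread criteria the post-exchange global spread is a
  convex piecewise-linear function of the transferred weight
  δ = w_a − w_b, so the best achievable exchange lies adjacent to the
  continuous minimizer and a two-pointer walk over the two sorted lists
  finds it in O(n_i + n_j). Equivalence with exhaustive pair enumeration
  is property-tested. The label criterion has no scalar transfer
  structure and falls back to scanning all pairs between the two folds.
- **Tabu search**: per iteration, the globally best strictly-improving
  exchange is applied. If only equal-objective exchanges remain, one is
  accepted when it strictly reduces the maximum per-fold cluster count
  (reading "more flexibility" as freeing the most crowded fold — the mean
  count is invariant under exchanges, so only a spread reading is
  meaningful) and its cluster pair is not in a FIFO tabu memory (tenure
  50). Strict improvements cannot cycle; the tie rule together with the
  tabu memory and an iteration cap (10·C by default) guarantees
  termination. The final objective is never worse than the LPT seed.
- **Label balance** counts sequences per class label per fold and
  minimizes the summed per-label spread; LPT initialization still uses
  total weight, as no label-aware seeding rule is obviously better.

All tie-breaks are deterministic (cluster id, fold index); a seed enters
only if `randomize_ties` is explicitly enabled, so identical inputs and
configuration produce byte-identical outputs.

## Synthetic data generator

`generate_families` emulates a collection of homologous families: a
founder per family, members derived by independent per-site substitution
at rate 1 − intra_identity (to a uniformly random different symbol), so
expected member–member identity is intra_identity². Optional features: a
common ancestor for all founders (`ancestor_identity`), giving controlled
intermediate inter-family similarity, and geometric-length indels for
robustness tests only.

What it does **not** model: substitution-rate heterogeneity, indel-rich
evolution, recombination, composition bias, or real database redundancy
structure. Passing tests on this generator demonstrate the pipeline's
structural guarantees and estimator calibration, not performance claims
on any real organism's data.

Fixture scales used by the tests and the acceptance script, chosen to
keep the exact O(n²) oracle cheap: 60 sequences (6 families × 10, 300 nt)
for the end-to-end unit checks, 300 sequences (30 families × 10, 600 nt,
intra_identity 0.995, ancestor_identity 0.992, k = 16, cosine, ε = 0.3,
P = 5) for the separation and split-regime checks. The ancestor identity
is calibrated from the Poisson mutation model so all inter-family
distances stay strictly below 0.7: this keeps the *inverted* regime
non-degenerate (with unrelated founders every inter-family distance is
1.0, the complement is 0, and inversion would chain the whole dataset
into one cluster). A side effect is that some inter-family distances fall
below ε and single linkage chains most families into one large cluster —
the separation guarantee is unaffected, but fold sizes on this fixture
are dominated by one cluster, which the run reports with a granularity
warning.

The exact-distance oracle shares no code with the sketching path (naive
string sets, naive arithmetic) so agreement between the two is a genuine
dual-route check.

## Numerical and degenerate-input choices

- Distances are computed in double precision directly from integer set
  sizes; no accumulation occurs, so the only rounding is in the final
  division/log.
- Sequences shorter than k contribute an empty k-mer set (distance 1.0 to
  everything, with a warning), not an error.
- P greater than the number of clusters leaves some folds empty and
  warns; a cluster heavier than total/P caps achievable balance and
  warns.
- Fold indices are 0-based internally and 1-based in all user-facing
  output.

## Known limitations

- The all-vs-all loop is pure Python and quadratic; it is comfortable to
  ~10⁴ sequences on one core. Scaling further needs the Hobohm
  pre-clustering path (with its weakened guarantee).
- The inverse-coverage measure is a documented placeholder (above).
- The leakage guarantee is relative to the *sketch* distance actually
  used. Sub-sampled sketches (MinHash/minimizer/prefix) estimate the full
  k-mer distance, so with aggressive sub-sampling a pair can fall just
  below ε in exact distance yet just above it in sketch distance; the
  audit and the guarantee are exact only in full mode.
- Hobohm 1 absorption can place sequences within ε of each other into
  different folds (absorbed members are only threshold-bounded to their
  representative).
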