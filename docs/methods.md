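# Methods

`protolex` detects translations of biomedical terms between a source and a
target language. It never compares strings across languages directly;
instead each language gets its own feature space, a linear map is learned
between the two reduced spaces from a small seed bilingual lexicon, and a
probabilistic classifier scores candidate pairs. This note records the
models, the parameters that matter, the numerical conventions, and what the
synthetic benchmarks do and do not show.

## Monolingual term representation

Each term is a non-negative feature vector built from one of two families:

* **Character n-grams (intrinsic).** All contiguous substrings of length
  `n_min=2` to `n_max=5`, binary-valued (presence only). The vocabulary
  keeps the `vocab_size=10,000` n-grams contained in the most lexicon terms
  (term-level presence, not token frequency — this matches the selection
  criterion used for contextual features and keeps the two families
  symmetric). Terms are case-folded and NFC-normalized; internal spaces of
  multi-word terms are kept as characters, preserving word-boundary
  information; no boundary padding is added.
* **Contextual PPMI features (extrinsic).** For every corpus occurrence of
  a term, the `window_before=2` preceding and `window_after=2` succeeding
  tokens contribute unigrams, plus the bigrams lying wholly inside one
  side's window (bigrams never span across the term). One term occurrence
  is one *context*; p(c), p(w) and p(c, w) are estimated as context-count
  ratios, and the feature value is PPMI(c, w) = max(0, log p(c,w)/(p(c)p(w))).
  Natural log by default; the base only rescales the matrix. Candidate
  features are cut to the `vocab_size` features extracted from the most
  distinct terms. Feature vocabularies are selected **per language** —
  each language owns its feature space, which is what the cross-lingual
  mapping step presumes.

Tokenization is whitespace splitting of case-folded NFC text. Ranking ties
in vocabulary selection are broken lexicographically so identical inputs
always give identical vocabularies.

## Prototype Vector Projection

Both feature families produce very sparse, very high-dimensional vectors.
PVP reduces dimensionality by choosing `d` *actual data vectors* as basis
directions: iteratively, the centroid **c** of the not-yet-selected vectors
is formed and every remaining vector **x** is scored by
s(**x**, **c**) = #{j : x_j c_j ≠ 0}; the argmax is selected and removed.
Removing selected prototypes from the centroid pool pushes later picks
toward different supports, increasing diversity. The selected prototypes
are Gram-Schmidt orthonormalized in selection order, and every vector is
projected by its inner products with the basis.

Implementation notes:

* For non-negative data the centroid's support equals the union support of
  the remaining vectors, so scores are maintained incrementally (the
  selection is exactly the literal recompute-the-centroid loop, verified
  against it in tests, but runs in O(d·n + nnz) updates).
* Ties in the argmax go to the lowest original row index.
* Gram-Schmidt is run with a re-orthogonalization pass (numerically
  equivalent to classical Gram-Schmidt, stable in floating point). A
  residual norm below `1e-10` marks the vector as dependent; dependent
  prototypes are discarded and the selection loop continues with the
  next-best vector, so the basis always reaches rank `d` or fails loudly.
* The default projection uses the orthonormal basis. A
  `raw_prototypes=True` mode projects onto the un-orthonormalized
  prototypes instead; with non-negative inputs this keeps all projected
  coordinates non-negative (the orthonormalized basis cannot guarantee
  that, since Gram-Schmidt introduces signed directions). Both modes are
  exact linear maps.

On the centroid score, one correction is worth stating plainly: for
non-negative vectors the centroid score *upper-bounds* the average
per-vector score, s(**c**(X), **y**) ≥ (1/n) Σᵢ s(**x**ᵢ, **y**), with
equality when all vectors share a common support — but equality does not
hold in general (y=(1,1), x₁=(1,0), x₂=(0,1): average 1, centroid score 2).
The test suite asserts the inequality and the shared-support equality, not
the general equality.

Comparison reductions behind the same interface: **L2** (top-d rows by
Euclidean norm as prototypes, then the same orthonormalize-and-project
path), **SVD** (rank-d scores U_d D_d with negative entries zeroed, the
standard remedy for negative cosine similarities in latent semantic
indexing), and **NMF** (rows of W from X ≈ WH). NMF uses the
multiplicative-update solver with a dense random positive initialization
(seed 0, `max_iter=500`, `tol=1e-4` by default); multiplicative updates
keep iterates strictly positive, so W is dense up to floating-point
underflow. Projection density is therefore convergence-dependent for NMF:
loosely converged runs and small d give ~100% dense W, while long runs at
large d underflow many entries to zero (~50% at d=500 on the sparse
synthetic set). The SVD density is stably ~50% (signs of the score entries
are symmetric), and the orthonormal-basis PVP projection is nearly fully
dense (~98% at d=500), while the raw-prototype PVP projection is ~38%
dense there. These measured densities are what the package's own
benchmarks print; they depend on d, on the data sparsity, and (for NMF) on
solver and stopping rule.

## Cross-lingual mapping (two-block NIPALS PLSR)

Given N seed pairs with reduced vectors arranged in rows of X (n×d_s) and Y
(n×d_t), partial least squares regression extracts r components: γ is
initialized from a Y column, then v = X'γ/‖·‖, λ = Xv, q = Y'λ/‖·‖,
γ = Yq is iterated to a fixed point (relative change in γ below `1e-8`,
at most 500 iterations); the loading p = X'λ/(λ'λ) and inner coefficient
c = λ'γ/(λ'λ) are recorded, and both blocks are deflated
(X ← X − λp', Y ← Y − cλq'). The mapping matrix is assembled as
M = V(P'V)⁻¹CQ' and applied in the row-vector sense, ŷ = w M. With r equal
to the rank of X the fit coincides with ordinary least squares (a test
asserts this to 1e-6 relative); smaller r regularizes, which is the point
when the seed lexicon is small. Default r = 10, the low end of the
practical 10–100 range.

Design choices that were genuinely open:

* The inner coefficient is the standard regression form; a sign-only form
  c = λ'γ/|λ'γ| exists in some write-ups of the two-block recursion but
  cannot reproduce magnitudes in the Y-deflation and destroys the
  least-squares limit, so it is kept only behind `inner="sign"`.
* Initialization is deterministic (the largest-norm Y column) rather than
  a random column; the fixed point is initialization-independent for
  non-degenerate data (tested), and determinism makes runs reproducible.
  `init="random"` restores the randomized variant.
* No mean-centering by default — the reduced vectors are non-negative and
  the recursion contains no centering step; `center=True` fits on centered
  blocks and adds the offsets back at prediction.
* Degenerate components (zero-norm intermediates, e.g. an exactly zero Y
  block) truncate the extraction with a warning; an all-zero Y yields the
  zero map.

## Pair classifier and ranking

A candidate pair (w_S, w_T) is encoded as the concatenation
[w̃_S; w̃_T; w̃_S M] of length d_s + 2 d_t. Positives are the seed pairs;
negatives are uniformly re-paired source/target terms, sampled with
rejection so that no negative coincides with a known positive, in equal
number to the positives. A 150-tree random forest is trained on these and
its positive-class probability is the similarity score; candidates are
ranked by descending score with lexicographic tie-breaks. A forest (rather
than a linear model) matters because the signal is the *agreement* between
the target block and the mapped-source block — an interaction that
axis-aligned splits can express but a linear scorer cannot; a linear mode
is deliberately not provided. Tree hyperparameters other than the count
follow scikit-learn defaults. All randomness (negative sampling, forest)
is seeded; fixed seeds give byte-identical rankings.

## Evaluation

* **Neighbor preservation** (for reductions): for every anchor, cosine
  similarities to the other n−1 vectors before and after projection are
  compared by Pearson's r (values) and Kendall's τ (orderings), computed
  from the concordant-pair count C as τ = 4C/((n−1)(n−2)) − 1, then
  averaged over anchors. Similarity ties — frequent, because sparse
  vectors often have exactly zero cosine — are broken by neighbor index on
  both sides, making both orderings genuine permutations. A zero vector is
  defined to have cosine 0 to everything. This tie-broken τ is an honest
  ceiling: when a projection is a perfect isometry the before/after
  *values* agree (r̄ = 1) but tiny floating-point noise reorders the
  tied-at-zero block, so τ̄ saturates well below 1 on very sparse data.
* **Precision@R** (for translation ranking): the fraction of the top-R
  candidates that are correct, averaged over queries; when R exceeds the
  list length the available prefix is used, with a warning.

## Synthetic data

Two generators stand in for the external data the real evaluation needs:

* `gen_sparse_vectors` — the reduction benchmark: 1000 vectors × 1000 (or
  10,000) dimensions, elements uniform on [0, 1) and independently zeroed
  with probability 0.98, i.e. ~98% zeros, the sparsity regime of n-gram and
  contextual term vectors. (Half-open [0, 1) instead of closed [0, 1]: a
  measure-zero difference.)
* `gen_planted_bilingual` — a stand-in bilingual lexicon with known ground
  truth: sparse non-negative source vectors, a planted sparse non-negative
  map B (both at zero-probability 0.9 — sparse enough to be term-like,
  dense enough that rows are informative at d≈50), targets
  X_T = max(0, X_S B + ε) with Gaussian noise σ (default 0.05, a
  non-trivial but solvable recovery task), identity alignment, and
  optional distractor target rows generated as images of withheld source
  vectors so they are plausible decoys rather than random noise.

What these benchmarks show: that the selection, orthonormalization,
mapping, and ranking machinery is correct, and how the reductions compare
under controlled sparsity. What they do not show: anything about real
morphology, genre, polysemy, or the asymmetry of real bilingual lexicons —
planted data is linearly generated by construction, so pipeline recovery
there is a correctness check, not a performance claim for real corpora.

## Problem sizes used by the test suite

The shipped tests run the reduction density comparison on the full
1000×1000 synthetic set at d=500; the neighbor-preservation trend
comparison on a 300×1000 subset at d ∈ {50, 150, 300} (300 anchors × 299
neighbors keeps the τ computation exact and quick); and the end-to-end
planted-translation recovery at n=500 training pairs, d_s = d_t = 50,
σ = 0, 500 distractors, 100 held-out queries, with the PLSR rank set to
d_s (the noise-free, fully identified regime). Oracle tests (Kendall τ
against exhaustive concordance enumeration, Pearson against the direct
formula, projection against explicit inner products, selection against the
literal centroid-recomputation loop) run on instances small enough to
enumerate.

## Known limitations

* The real four-language evaluation requires an external Wikipedia/UMLS-
  derived dataset; the pipeline accepts such data through the I/O formats
  but none is bundled.
* NMF projection density is not a single number — see above; comparisons
  quoting "NMF is ~100% dense" hold only for loosely-converged solutions
  or small d relative to the data rank.
* The claim that L1 and L2 norms induce the same prototype ordering is not
  true in general ((3,0) vs (2,2)); the L2 baseline is exactly top-d by
  Euclidean norm and no L1 equivalence is asserted.
* Kendall τ̄ values on very sparse data are depressed by the tie-broken
  zero-similarity block and should be compared between methods at equal d,
  not read as absolute rank-correlation quality.
* Probability calibration of the forest scores is out of scope; scores
  order candidates but are not calibrated translation probabilities.
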