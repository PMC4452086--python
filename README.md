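# protolex

Cross-lingual detection of biomedical term translations. Given monolingual
term lexicons for a source and a target language (plus, optionally,
corpora for contextual features) and a small seed list of known
translation pairs, `protolex` ranks target-language candidates for each
source term so that a human annotator inspects a short list instead of an
entire lexicon. It is aimed at people building bilingual biomedical
dictionaries and at anyone who needs a non-negative, prototype-based
dimensionality reduction for very sparse feature vectors.

## Method

1. **Monolingual features.** Each term w is a non-negative vector
   **w** ∈ ℝ^m: binary character n-grams (n = 2..5) from the term string,
   or PPMI-weighted contextual unigrams/bigrams from a ±2-token window
   around corpus occurrences, with
   PPMI(c, w) = max(0, log p(c,w)/(p(c)p(w))).
2. **Prototype Vector Projection (PVP).** To reduce ℝ^m to ℝ^d, PVP picks
   d actual data vectors as prototypes: repeatedly score every remaining
   vector **x** against the centroid **c** of the remaining set by
   s(**x**, **c**) = #{j : x_j c_j ≠ 0}, take the argmax, remove it,
   recompute. The prototypes are Gram-Schmidt orthonormalized into
   p_1..p_d and every vector is projected as x̃ = [x·p_1, …, x·p_d].
   L2-norm prototype selection, zero-clipped truncated SVD (U_d D_d) and
   NMF are provided as baselines behind the same interface.
3. **Cross-lingual map.** From the reduced seed pairs, a two-block NIPALS
   partial least squares regression extracts r covariance-maximal
   components and assembles M = V(P'V)⁻¹CQ', a linear map from the
   reduced source space to the reduced target space (ŷ = w̃_S M).
4. **Similarity and ranking.** A 150-tree random forest classifies pair
   vectors [w̃_S; w̃_T; w̃_S M] (seed pairs vs randomly re-paired
   negatives); its positive-class probability is the similarity
   sim(w_S, w_T), and candidates are ranked by it.

Evaluation utilities compute neighbor-preservation statistics for the
reductions (mean Pearson r and mean Kendall τ = 4C/((n−1)(n−2)) − 1 over
before/after cosine-similarity neighborhoods) and Precision@R for ranked
translations. Synthetic generators (sparse uniform vectors with 98% zeros;
planted-linear-map bilingual data) make the whole pipeline testable
without external data. See `docs/methods.md` for assumptions, parameter
defaults, and numerical conventions.

## Worked example

`examples/04_translation_ranking.py` builds a planted bilingual world
(250 aligned pairs, 30-dimensional reduced vectors, 100 distractor
targets), fits the PLSR map on 200 pairs, trains the forest, and ranks
candidates for held-out queries:

```
fitted rank-30 PLSR map (30 -> 30)

top-5 candidates for src00200 (true translation: tgt00200):
  tgt00200  0.727  <-- correct
  tgt00227  0.693
  tgt00225  0.633
  tgt00233  0.540
  tgt00224  0.533

top-1 accuracy over 50 held-out queries: 41/50
```

The scores are forest probabilities in [0, 1]; the true translation tops
the list because its target block agrees with the mapped-source block.
The other examples show feature extraction (`01`), the density profiles of
the four reductions (`02` — e.g. at d=100 on 2%-dense data: PVP 97.9%,
SVD 49.9%, NMF 90.5% non-zero), and the neighbor-preservation comparison
(`03` — PVP's mean τ keeps rising with d while SVD/NMF saturate).

A thin CLI mirrors the pipeline stages
(`protolex featurize | reduce | fit-map | train | rank | eval | simulate`);
run `protolex --help`.

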