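"""Full cross-lingual translation-ranking pipeline on planted data.

Source vectors are mapped into the target space by a PLSR-learned linear
map; a random forest scores [source; target; mapped-source] pair vectors;
candidates are ranked by the positive-class probability. The planted
bilingual generator provides ground truth, so we can measure how often the
true translation is ranked first.
"""

import numpy as np

from protolex import (
    PairList,
    TermLexicon,
    TrainingBlock,
    fit_plsr,
    gen_planted_bilingual,
    rank_candidates,
    sample_negative_pairs,
    train_similarity_model,
)

data = gen_planted_bilingual(
    n=250, d_s=30, d_t=30, sparsity=0.9, sigma=0.0, seed=2, n_distractors=100
)
src = {t: data.X_S[i] for i, t in enumerate(data.source_terms)}
tgt = {t: data.X_T[i] for i, t in enumerate(data.target_terms)}
train_pairs = PairList(pairs=data.pairs.pairs[:200])
test_pairs = data.pairs.pairs[200:]

X = np.array([src[s] for s, _ in train_pairs])
Y = np.array([tgt[t] for _, t in train_pairs])
pmap = fit_plsr(TrainingBlock(X, Y), r=30)
print(f"fitted rank-{pmap.rank} PLSR map ({pmap.source_dim} -> {pmap.target_dim})")

negatives = sample_negative_pairs(
    train_pairs,
    TermLexicon("src", tuple(s for s, _ in train_pairs)),
    TermLexicon("tgt", tuple(t for _, t in train_pairs)),
    seed=2,
)
model = train_similarity_model(
    train_pairs, negatives, src, tgt, pmap, n_trees=150, seed=2
)

pool = {t: tgt[t] for t in data.target_terms[200:]}  # held-out + distractors
query, truth = test_pairs[0]
ranked = rank_candidates(model, query, src[query], pool, k=5)
print(f"\ntop-5 candidates for {query} (true translation: {truth}):")
for term, score in ranked.ranking:
    marker = "  <-- correct" if term == truth else ""
    print(f"  {term}  {score:.3f}{marker}")

hits = sum(
    rank_candidates(model, s, src[s], pool, k=1).ranking[0][0] == t
    for s, t in test_pairs
)
print(f"\ntop-1 accuracy over {len(test_pairs)} held-out queries: "
      f"{hits}/{len(test_pairs)}")
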