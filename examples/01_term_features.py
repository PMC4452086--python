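"""Build monolingual feature vectors for a tiny English term lexicon.

Character n-grams need only the term strings; contextual PPMI features
additionally need a tokenized corpus.
"""

from protolex import (
    ContextConfig,
    Corpus,
    NgramConfig,
    TermLexicon,
    build_ngram_matrix,
    extract_char_ngrams,
    extract_context_counts,
    ppmi_weight,
)

lexicon = TermLexicon(
    language="en",
    terms=("catecholamine", "syndrome", "heart attack", "neuron"),
)

grams = sorted(extract_char_ngrams("catecholamine", NgramConfig()))
print(f"'catecholamine' yields {len(grams)} distinct 2-5-grams, e.g.:")
print("  ", ", ".join(grams[:12]))

ngram_matrix = build_ngram_matrix(lexicon, NgramConfig(vocab_size=100))
print(
    f"n-gram matrix: {ngram_matrix.shape[0]} terms x "
    f"{ngram_matrix.shape[1]} binary features"
)

corpus = Corpus(
    documents=(
        tuple("elevated catecholamine levels were measured after surgery".split()),
        tuple("the patient suffered a heart attack last winter".split()),
        tuple("a heart attack damages the cardiac muscle".split()),
        tuple("each neuron fires when its potential crosses threshold".split()),
        tuple("this syndrome presents with elevated catecholamine secretion".split()),
    )
)
counts = extract_context_counts(corpus, lexicon, ContextConfig(vocab_size=50))
ppmi = ppmi_weight(counts)
print(
    f"context matrix: {ppmi.shape[0]} terms x {ppmi.shape[1]} PPMI features "
    f"from {counts.total_contexts} term occurrences"
)
row = dict(zip(lexicon.terms, ppmi.toarray()))
col = {c: j for j, c in enumerate(ppmi.vocabulary)}
val = row["catecholamine"][col["elevated"]]
print(f"PPMI('elevated', 'catecholamine') = {val:.4f}")
print(
    "positive PPMI means the word co-occurs with the term more often than "
    "independence would predict"
)
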