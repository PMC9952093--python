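"""Cluster a corpus of abstracts and inspect the thematic groups.

Builds a synthetic five-topic corpus with known labels, runs the full
review pipeline (clean -> stem -> TF-IDF -> silhouette-guided k-means),
and prints what it found.
"""

from litmine import (
    GeneratorConfig,
    fit_vocabulary,
    generate_labeled_corpus,
    preprocess_corpus,
    sweep_k,
    tfidf,
    top_words,
)

corpus, true_labels = generate_labeled_corpus(GeneratorConfig(seed=0))
tokens = preprocess_corpus(corpus)
matrix = tfidf(tokens, fit_vocabulary(tokens))
report = sweep_k(matrix, k_min=2, k_max=16, seed=0, n_init=10)
result = report.results[report.chosen_k]

print(f"{len(corpus)} documents, vocabulary of {matrix.n_terms} stems")
print(f"silhouette-guided choice: k={report.chosen_k} "
      f"(feasible: {list(report.feasible_ks)})")
print(f"cluster sizes: {[int(s) for s in result.sizes]}")
for c in range(result.k):
    members = [t for t, lab in zip(tokens, result.labels) if lab == c]
    table = top_words(members, n=3, scope=f"cluster {c}")
    terms = ", ".join(table.terms)
    print(f"  cluster {c}: top stems {terms}")
print("Top stems per cluster identify each cluster's theme; a real corpus"
      " shows e.g. 'extract'/'antibacteri' vs 'soil'/'fire' clusters.")
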