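"""Disease semantic similarity from an ontology DAG plus annotation corpora.

Builds a tiny disease hierarchy by hand, attaches annotation counts from a
disease-gene-style corpus, and prints the information-content similarity of
three disease pairs.
"""
from knmbp import CorpusAnnotation, DiseaseDAG, normalize_frequency, propagate_frequency, semantic_similarity_pair

# root <- {cancer, metabolic}; cancer <- {colon_ca, lung_ca}
dag = DiseaseDAG.from_edges(
    [
        ("cancer", "disease"),
        ("metabolic", "disease"),
        ("colon_ca", "cancer"),
        ("lung_ca", "cancer"),
        ("diabetes", "metabolic"),
    ]
)
corpus = CorpusAnnotation(
    "disease-gene", {"colon_ca": 12, "lung_ca": 9, "diabetes": 7, "cancer": 3}
)

ft = propagate_frequency(dag, corpus)
pt = normalize_frequency(ft, dag)
print(f"accumulated frequency at the root: {ft[dag.root]:.0f}")
for d1, d2 in [("colon_ca", "lung_ca"), ("colon_ca", "diabetes"), ("colon_ca", "colon_ca")]:
    s = semantic_similarity_pair(pt, dag, d1, d2)
    print(f"similarity({d1}, {d2}) = {s:.4f}")

# The two cancers share the informative ancestor 'cancer', so their
# similarity is high; colon_ca vs diabetes only share the root (similarity
# 0); every term is maximally similar to itself.
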