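"""miRNA functional similarity from a weighted gene network and target sets.

Normalizes a toy log-likelihood gene network, then compares miRNAs through
the best-match similarity of their target gene sets.
"""
from knmbp import mirna_functional_similarity, normalize_gene_network

net = normalize_gene_network(
    [
        ("TP53", "MDM2", 4.0),   # carries the maximum score -> similarity 1
        ("TP53", "CDKN1A", 2.0),
        ("MDM2", "CDKN1A", 1.0),
        ("INS", "IGF1", 3.0),
    ]
)
print(f"normalized gene similarity TP53-MDM2: {net.similarity('TP53', 'MDM2'):.2f}")

targets = {
    "mir-a": {"TP53", "MDM2"},
    "mir-b": {"MDM2", "CDKN1A"},
    "mir-c": {"INS", "IGF1"},
}
sf = mirna_functional_similarity(targets, net)
for pair in [("mir-a", "mir-b"), ("mir-a", "mir-c")]:
    print(f"functional similarity{pair} = {sf.loc(*pair):.4f}")

# mir-a and mir-b target overlapping, strongly linked genes and score high;
# mir-c regulates an unrelated module, so its similarity to mir-a is 0.
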