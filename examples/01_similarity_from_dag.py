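"""Disease semantic similarity from a toy ontology, then lncRNA functional
similarity from known associations.

Two diseases that share a close ancestor in the DAG get a high semantic
similarity; two lncRNAs whose associated-disease sets match well under that
similarity get a high functional similarity.
"""

import numpy as np

from hetwalk import AssociationMatrix, DiseaseOntology, build_lfs, compute_dss

# a small DAG: two disease families under one root
edges = [
    ("lung_cancer", "respiratory_disease"),
    ("asthma", "respiratory_disease"),
    ("colon_cancer", "digestive_disease"),
    ("crohns", "digestive_disease"),
    ("respiratory_disease", "disease_root"),
    ("digestive_disease", "disease_root"),
]
ontology = DiseaseOntology.from_edges(edges, delta=0.5)
dss = compute_dss(ontology)

print("semantic similarity (contribution decay 0.5 per DAG edge):")
for a, b in [("lung_cancer", "asthma"), ("lung_cancer", "colon_cancer")]:
    print(f"  DSS({a}, {b}) = {dss.values[dss.index(a), dss.index(b)]:.4f}")

# three lncRNAs with overlapping disease sets
ld = AssociationMatrix(
    ["lncA", "lncB", "lncC"],
    ["lung_cancer", "asthma", "colon_cancer"],
    np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]]),
)
lfs = build_lfs(ld, dss)
print("\nfunctional similarity (best-match average over disease sets):")
for i, j in [(0, 1), (0, 2)]:
    print(f"  LFS({ld.row_ids[i]}, {ld.row_ids[j]}) = {lfs.values[i, j]:.4f}")
print("\nlncA and lncB share lung cancer, so they are far more similar than")
print("lncA and lncC, which only meet through the distant common root.")
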