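"""Frequency and homology baselines, and score combination.

The naive classifier scores every query with per-class training
frequencies; the homology baseline transfers annotations from similar
sequences weighted by bitscore; the combined predictor averages two score
matrices cellwise.
"""

from pufun import (
    AnnotationTable,
    ClassIndex,
    SimilarityHits,
    combine_scores,
)
from pufun.baselines import diamond_transfer_scores, naive_score_matrix

train_ann = AnnotationTable.from_records([
    ("s1", "T:binding", "EXP"),
    ("s2", "T:binding", "EXP"), ("s2", "T:catalysis", "EXP"),
    ("s3", "T:catalysis", "EXP"),
    ("s4", "T:binding", "EXP"),
], propagated=True)
index = ClassIndex(namespace="molecular_function", terms=["T:binding", "T:catalysis"])

naive = naive_score_matrix(train_ann, index, ["query1"])
print("naive scores (training frequencies):")
print(dict(zip(index.terms, naive.values[0].round(3))))

hits = SimilarityHits.from_records([
    ("query1", "s1", 1e-40, 200.0),  # strong hit, annotated {binding}
    ("query1", "s2", 1e-5, 50.0),    # weaker hit, {binding, catalysis}
])
homology = diamond_transfer_scores(hits, train_ann, index, ["query1"])
print("homology-transfer scores (bitscore-weighted vote):")
print(dict(zip(index.terms, homology.values[0].round(3))))

combined = combine_scores(naive, homology)
print("combined (cellwise mean):")
print(dict(zip(index.terms, combined.values[0].round(3))))
# binding is supported by both evidence sources; catalysis only by the
# weaker homolog, so its combined score stays low.
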