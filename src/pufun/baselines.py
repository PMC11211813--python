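"""Frequency and homology-transfer baselines, and score combination.

The naive classifier assigns every query protein the same score per class,
namely the class's training annotation frequency N_f / N_total.  The
homology baseline transfers propagated annotations from similar training
sequences, weighting each hit by its normalized bitscore:

    S(p, f) = sum_s bitscore(p, s) * 1[f in T_s] / sum_s bitscore(p, s)

over hits with e-value <= 0.001.  Combining two predictors takes the
cellwise arithmetic mean of their score matrices.
"""

from __future__ import annotations

import numpy as np

from .datasets import SimilarityHits, DEFAULT_EVALUE_MAX
from .nn import ScoreMatrix
from .ontology import AnnotationTable, ClassIndex, class_frequencies


def naive_scores(train_ann: AnnotationTable, index: ClassIndex) -> np.ndarray:
    """Per-class frequency scores, identical for every query protein."""
    return class_frequencies(train_ann, index).frequencies.copy()


def naive_score_matrix(
    train_ann: AnnotationTable, index: ClassIndex, queries: list[str]
) -> ScoreMatrix:
    row = naive_scores(train_ann, index)
    return ScoreMatrix(
        list(queries), index, np.tile(row, (len(queries), 1)), kind="probability"
    )


def diamond_transfer_scores(
    hits: SimilarityHits,
    train_ann: AnnotationTable,
    index: ClassIndex,
    queries: list[str],
    e_max: float = DEFAULT_EVALUE_MAX,
) -> ScoreMatrix:
    """Bitscore-weighted annotation transfer from similar training proteins.

    Only hits whose subject carries (propagated) training annotations
    contribute; queries with no retained hits get an all-zero row.
    """
    if not train_ann.propagated:
        raise ValueError("homology transfer uses propagated training annotations")
    prot_terms = train_ann.protein_terms()
    values = np.zeros((len(queries), len(index)))
    qpos = {q: i for i, q in enumerate(queries)}
    df = hits.df
    kept = df[(df["evalue"] <= e_max) & df["subject"].isin(prot_terms)]
    weight_total = np.zeros(len(queries))
    for q, s, bits in zip(kept["query"], kept["subject"], kept["bitscore"]):
        i = qpos.get(q)
        if i is None:
            continue
        weight_total[i] += bits
        for term in prot_terms[s]:
            j = index.position.get(term)
            if j is not None:
                values[i, j] += bits
    nz = weight_total > 0
    values[nz] /= weight_total[nz, None]
    return ScoreMatrix(list(queries), index, values, kind="probability")


def combine_scores(a: ScoreMatrix, b: ScoreMatrix) -> ScoreMatrix:
    """Cellwise arithmetic mean over the union of both protein universes.

    A protein absent from one operand contributes 0 for that operand, which
    keeps combined scores conservative for proteins without homology hits.
    """
    if a.index.terms != b.index.terms:
        raise ValueError("score matrices use different class indices")
    proteins = sorted(set(a.proteins) | set(b.proteins))
    k = len(a.index)
    out = np.zeros((len(proteins), k))
    for op in (a, b):
        pos = {p: i for i, p in enumerate(proteins)}
        for src_i, prot in enumerate(op.proteins):
            out[pos[prot]] += op.values[src_i]
    out *= 0.5
    kind = "probability" if a.kind == b.kind == "probability" else "logit"
    return ScoreMatrix(proteins, a.index, out, kind=kind)
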