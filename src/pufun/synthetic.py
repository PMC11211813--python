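"""Synthetic data with the statistical structure PU learning assumes.

The generator emulates the real pipeline's inputs without any downloads: a
random DAG ontology, Gaussian protein embeddings, complete ("true")
annotations produced by per-term logistic models and closed upward under the
true-path rule, and observed positives obtained by hiding each true direct
annotation independently with probability 1-c (the selected-completely-at-
random, SCAR, assumption with label frequency c).  Masking acts on *direct*
annotations and the survivors are re-propagated — mirroring how curators add
leaf-level annotations whose ancestors follow by the true-path rule.

Because masking is independent of the embedding, the observed positives are
an unbiased subsample of the true positives per class, which is exactly the
premise under which the uPU risk estimator is unbiased; the generator is
therefore the test bed for that property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .datasets import LabelMatrix, SimilarityHits
from .nn import EmbeddingMatrix
from .ontology import AnnotationTable, ClassIndex, OntologyDAG, serialize_obo

SYNTHETIC_NAMESPACE = "molecular_function"


def _term_name(i: int) -> str:
    return f"T:{i:04d}"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``weight_scale`` is the standard deviation of the per-term logistic
    score w_t . x over the embedding distribution (the class-conditional
    signal strength); ``target_rate`` sets the per-term bias so that a
    zero-signal term would be a direct positive at this marginal rate;
    ``label_frequency`` is the SCAR probability c that a true direct
    positive is observed.
    """

    n_terms: int = 30
    max_parents: int = 2
    n_proteins: int = 1000
    dim: int = 32
    weight_scale: float = 2.0
    target_rate: float = 0.15
    label_frequency: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("need at least 2 terms")
        if not 0.0 < self.label_frequency <= 1.0:
            raise ValueError("label frequency c must lie in (0, 1]")
        if self.dim < 1:
            raise ValueError("embedding dim must be >= 1")
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must lie in (0, 1)")


@dataclass
class SyntheticDataset:
    """A complete synthetic instance: ontology, features, true and PU labels."""

    dag: OntologyDAG
    embeddings: EmbeddingMatrix
    true_direct: LabelMatrix
    true_labels: LabelMatrix      # propagated, complete
    observed_labels: LabelMatrix  # propagated, SCAR-masked
    config: SyntheticConfig

    @property
    def true_priors(self) -> np.ndarray:
        """Per-class true prior pi*_i = column mean of the complete labels."""
        return self.true_labels.values.mean(axis=0)


def simulate_ontology(n_terms: int, max_parents: int = 2, seed: int = 0) -> OntologyDAG:
    """Random single-namespace DAG, acyclic by construction.

    Term 0 is the root; term j >= 1 draws 1..max_parents distinct parents
    uniformly from terms 0..j-1.  A small fraction of edges are labelled
    ``part_of`` instead of ``is_a`` to exercise typed-edge handling.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[tuple[str, str]]] = {}
    namespace = {_term_name(i): SYNTHETIC_NAMESPACE for i in range(n_terms)}
    for j in range(1, n_terms):
        n_par = int(rng.integers(1, min(max_parents, j) + 1))
        chosen = rng.choice(j, size=n_par, replace=False)
        edges = set()
        for p in np.sort(chosen):
            rel = "part_of" if rng.random() < 0.15 else "is_a"
            edges.add((_term_name(int(p)), rel))
        parents[_term_name(j)] = edges
    return OntologyDAG(parents=parents, namespace=namespace)


def full_class_index(dag: OntologyDAG, namespace: str = SYNTHETIC_NAMESPACE) -> ClassIndex:
    """Index over every non-obsolete term of the namespace (lexicographic)."""
    terms = sorted(
        t for t, ns in dag.namespace.items()
        if ns == namespace and t not in dag.obsolete
    )
    return ClassIndex(namespace=namespace, terms=terms)


def _propagate_matrix(dag: OntologyDAG, index: ClassIndex, direct: np.ndarray) -> np.ndarray:
    """Upward closure of a direct-annotation matrix along ontology edges."""
    out = direct.astype(np.int8).copy()
    for j, term in enumerate(index.terms):
        anc = dag.ancestors(term)
        cols = [index.position[a] for a in anc if a in index.position]
        if cols:
            np.maximum.at(out.T, cols, out[:, j])
    return out


def propagate_label_matrix(dag: OntologyDAG, labels: LabelMatrix) -> LabelMatrix:
    """Return the upward-closed version of a label matrix."""
    return LabelMatrix(
        proteins=labels.proteins,
        index=labels.index,
        values=_propagate_matrix(dag, labels.index, labels.values),
    )


def simulate_proteins(
    dag: OntologyDAG,
    n: int,
    d: int,
    weight_scale: float = 2.0,
    target_rate: float = 0.15,
    seed: int = 0,
    return_weights: bool = False,
):
    """Draw embeddings and complete true labels.

    Embeddings are i.i.d. standard normal.  Every non-root term t carries a
    weight vector w_t with ||w_t||-induced score s.d. ``weight_scale`` and a
    bias logit(``target_rate``); protein p is a *direct* positive for t with
    probability sigmoid(w_t . x_p + b_t).  Direct positives are propagated
    upward to produce the complete matrix.

    Returns ``(embeddings, direct_labels, complete_labels)``, plus the
    weight matrix and bias when ``return_weights`` is set.
    """
    rng = np.random.default_rng(seed)
    index = full_class_index(dag)
    k = len(index)
    X = rng.standard_normal((n, d))
    W = rng.standard_normal((d, k)) * (weight_scale / np.sqrt(d))
    b = logit(target_rate)
    roots = dag.roots()
    for j, term in enumerate(index.terms):
        if term in roots:
            W[:, j] = 0.0
    prob = expit(X @ W + b)
    for j, term in enumerate(index.terms):
        if term in roots:
            prob[:, j] = 0.0  # roots receive no direct annotations
    direct = (rng.random((n, k)) < prob).astype(np.int8)
    proteins = [f"P{i:05d}" for i in range(n)]
    emb = EmbeddingMatrix(proteins, X)
    direct_lm = LabelMatrix(proteins, index, direct)
    complete = LabelMatrix(proteins, index, _propagate_matrix(dag, index, direct))
    if return_weights:
        return emb, direct_lm, complete, W, b
    return emb, direct_lm, complete


def apply_scar(
    true_direct: LabelMatrix,
    dag: OntologyDAG,
    c: float,
    seed: int = 0,
) -> LabelMatrix:
    """Hide each true direct positive independently with probability 1-c.

    The surviving direct positives are re-propagated upward; zeros of the
    result are unlabeled, not negative.  ``c=1`` reproduces the complete
    propagated matrix.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError("label frequency c must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(true_direct.values.shape) < c
    observed_direct = (true_direct.values.astype(bool) & keep).astype(np.int8)
    return LabelMatrix(
        proteins=true_direct.proteins,
        index=true_direct.index,
        values=_propagate_matrix(dag, true_direct.index, observed_direct),
    )


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full pipeline: ontology -> embeddings/true labels -> SCAR observation.

    Sub-seeds are derived deterministically from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    dag = simulate_ontology(config.n_terms, config.max_parents, seed=seeds[0])
    emb, direct, complete = simulate_proteins(
        dag,
        config.n_proteins,
        config.dim,
        weight_scale=config.weight_scale,
        target_rate=config.target_rate,
        seed=seeds[1],
    )
    observed = apply_scar(direct, dag, config.label_frequency, seed=seeds[2])
    return SyntheticDataset(
        dag=dag,
        embeddings=emb,
        true_direct=direct,
        true_labels=complete,
        observed_labels=observed,
        config=config,
    )


# ---------------------------------------------------------------------------
# Writers emitting the formats the real pipeline reads


def write_obo(dag: OntologyDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_obo(dag))


def annotation_table_from_labels(labels: LabelMatrix, evidence: str = "EXP") -> AnnotationTable:
    """Direct-annotation table for the 1-cells of a label matrix."""
    records = []
    for i, prot in enumerate(labels.proteins):
        for j in np.flatnonzero(labels.values[i]):
            records.append((prot, labels.index.terms[j], evidence))
    return AnnotationTable.from_records(records)


def write_hits_outfmt6(hits: SimilarityHits, path) -> None:
    """Write hits as 12-column BLAST/DIAMOND tabular output.

    The alignment-detail columns (identity, length, positions) are filled
    with placeholder values; only query/subject/e-value/bitscore carry
    information.
    """
    with open(path, "w") as fh:
        for q, s, ev, bits in hits.df.itertuples(index=False):
            fh.write(
                f"{q}\t{s}\t90.0\t100\t10\t0\t1\t100\t1\t100\t{ev:.3g}\t{bits:.1f}\n"
            )


def random_hits(
    proteins: list[str], n_hits: int, seed: int = 0
) -> SimilarityHits:
    """Random similarity hits — smoke-test input for the grouping/splitting
    code only; carries no homology structure."""
    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_hits):
        q, s = rng.choice(len(proteins), size=2, replace=True)
        evalue = float(10.0 ** rng.uniform(-30, 1))
        bitscore = float(rng.uniform(30, 300))
        recs.append((proteins[int(q)], proteins[int(s)], evalue, bitscore))
    return SimilarityHits.from_records(recs)
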