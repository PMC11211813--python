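import numpy as np
import pytest

from pufun.ontology import AnnotationTable, OntologyDAG
from pufun.synthetic import simulate_ontology


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """a <- b <- c (c is the most specific term)."""
    return OntologyDAG(
        parents={"T:b": {("T:a", "is_a")}, "T:c": {("T:b", "is_a")}},
        namespace={t: "molecular_function" for t in ("T:a", "T:b", "T:c")},
    )


@pytest.fixture
def random_dag() -> OntologyDAG:
    return simulate_ontology(n_terms=40, max_parents=3, seed=123)


def random_annotations(dag: OntologyDAG, n_proteins: int, rng: np.random.Generator,
                       mean_terms: float = 3.0) -> AnnotationTable:
    """Direct annotations drawn uniformly over non-root terms."""
    terms = sorted(t for t in dag.namespace if t not in dag.obsolete)
    records = []
    for i in range(n_proteins):
        k = 1 + rng.poisson(mean_terms)
        chosen = rng.choice(len(terms), size=min(k, len(terms)), replace=False)
        for j in chosen:
            records.append((f"P{i:03d}", terms[int(j)], "EXP"))
    return AnnotationTable.from_records(records)


def propagation_edges(dag: OntologyDAG) -> dict[str, set[str]]:
    """Plain parent-edge dict for the brute-force oracles."""
    return {t: dag.propagation_parents(t) for t in dag.namespace if t not in dag.obsolete}
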