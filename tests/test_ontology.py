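import math

import numpy as np
import pytest

from conftest import propagation_edges, random_annotations
from oracles import count_filter, ic_by_intersection, propagate_sets, reachable_fixpoint

from pufun.ontology import (
    AnnotationTable,
    FrequencyVector,
    OboParseError,
    build_class_index,
    class_frequencies,
    compute_priors,
    information_content,
    parse_obo,
    propagate_annotations,
    serialize_obo,
)
from pufun.synthetic import simulate_ontology


MINIMAL_OBO = """format-version: 1.2
ontology: synthetic

[Term]
id: T:1
name: root
namespace: molecular_function

[Term]
id: T:2
name: child
namespace: molecular_function
is_a: T:1
"""


class TestParseObo:
    def test_minimal_document(self):
        dag = parse_obo(MINIMAL_OBO)
        assert dag.terms == {"T:1", "T:2"}
        assert dag.propagation_parents("T:2") == {"T:1"}
        assert dag.roots() == {"T:1"}

    def test_obsolete_term_flagged_without_edges(self):
        doc = MINIMAL_OBO + "\n[Term]\nid: T:3\nnamespace: molecular_function\nis_obsolete: true\n"
        dag = parse_obo(doc)
        assert "T:3" in dag.terms
        assert "T:3" in dag.obsolete
        assert dag.propagation_parents("T:3") == set()

    def test_alt_id_resolution(self):
        doc = MINIMAL_OBO.replace("name: child", "name: child\nalt_id: T:9")
        dag = parse_obo(doc)
        assert dag.resolve("T:9") == "T:2"

    def test_cycle_raises_naming_member(self):
        doc = (
            "format-version: 1.2\n\n"
            "[Term]\nid: T:1\nnamespace: molecular_function\nis_a: T:2\n\n"
            "[Term]\nid: T:2\nnamespace: molecular_function\nis_a: T:1\n"
        )
        with pytest.raises(OboParseError, match="cyclic"):
            parse_obo(doc)

    def test_unparseable_line_reports_line_number(self):
        doc = MINIMAL_OBO + "\n[Term]\nid: T:4\nthis is not a tag value pair\n"
        with pytest.raises(OboParseError, match="line"):
            parse_obo(doc)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_serialization(self, seed):
        dag = simulate_ontology(n_terms=50, max_parents=3, seed=seed)
        back = parse_obo(serialize_obo(dag))
        assert back.namespace == dag.namespace
        assert back.obsolete == dag.obsolete
        for t in dag.namespace:
            assert back.parents.get(t, set()) == dag.parents.get(t, set())


class TestAncestors:
    def test_root_has_no_ancestors(self, chain_dag):
        assert chain_dag.ancestors("T:a") == set()

    def test_chain_is_transitive(self, chain_dag):
        assert chain_dag.ancestors("T:c") == {"T:b", "T:a"}

    def test_unknown_accession_raises(self, chain_dag):
        with pytest.raises(KeyError):
            chain_dag.ancestors("T:zzz")

    def test_matches_fixpoint_oracle_on_random_dag(self):
        dag = simulate_ontology(n_terms=100, max_parents=3, seed=7)
        edges = propagation_edges(dag)
        for term in dag.namespace:
            assert dag.ancestors(term) == reachable_fixpoint(edges, term)


class TestPropagation:
    def test_true_path_rule_on_chain(self, chain_dag):
        ann = AnnotationTable.from_records([("p1", "T:c", "EXP")])
        result = propagate_annotations(chain_dag, ann)
        assert result.protein_terms() == {"p1": {"T:c", "T:b", "T:a"}}
        assert result.propagated

    def test_idempotent_on_closed_set(self, chain_dag):
        ann = AnnotationTable.from_records(
            [("p1", t, "EXP") for t in ("T:a", "T:b", "T:c")]
        )
        once = propagate_annotations(chain_dag, ann)
        twice = propagate_annotations(chain_dag, once)
        assert once.protein_terms() == twice.protein_terms()

    def test_unresolvable_accession_listed(self, chain_dag):
        ann = AnnotationTable.from_records([("p1", "T:nope", "EXP")])
        with pytest.raises(KeyError, match="T:nope"):
            propagate_annotations(chain_dag, ann)

    def test_matches_per_term_oracle_union(self, random_dag):
        rng = np.random.default_rng(5)
        ann = random_annotations(random_dag, 30, rng)
        result = propagate_annotations(random_dag, ann)
        expected = propagate_sets(propagation_edges(random_dag), ann.protein_terms())
        assert result.protein_terms() == expected

    def test_upward_closed_and_count_monotone(self, random_dag):
        rng = np.random.default_rng(9)
        ann = propagate_annotations(random_dag, random_annotations(random_dag, 25, rng))
        pt = ann.protein_terms()
        for terms in pt.values():
            for t in terms:
                assert random_dag.ancestors(t) <= terms
        # N_child <= N_parent along every propagation edge
        counts = {t: sum(1 for ts in pt.values() if t in ts) for t in random_dag.namespace}
        for child in random_dag.namespace:
            for parent in random_dag.propagation_parents(child):
                assert counts[child] <= counts[parent]


class TestClassIndex:
    def make_table(self, counts):
        records = []
        for term, c in counts.items():
            for i in range(c):
                records.append((f"P{i}", term, "EXP"))
        return AnnotationTable.from_records(records, propagated=True)

    def test_min_count_thresholds(self, chain_dag):
        # T:a in 10 proteins, T:b in 2, T:c in 0
        ann = self.make_table({"T:a": 10, "T:b": 2})
        idx1 = build_class_index(chain_dag, ann, "molecular_function", min_count=1)
        assert idx1.terms == ["T:a", "T:b"]
        idx5 = build_class_index(chain_dag, ann, "molecular_function", min_count=5)
        assert idx5.terms == ["T:a"]

    def test_empty_vocabulary_raises(self, chain_dag):
        ann = self.make_table({"T:a": 1})
        with pytest.raises(ValueError):
            build_class_index(chain_dag, ann, "molecular_function", min_count=5)

    def test_membership_matches_counting_oracle(self, random_dag):
        rng = np.random.default_rng(21)
        ann = propagate_annotations(random_dag, random_annotations(random_dag, 40, rng))
        for mc in (1, 3, 8):
            idx = build_class_index(random_dag, ann, "molecular_function", min_count=mc)
            assert set(idx.terms) == count_filter(ann.protein_terms(), mc)
            assert idx.terms == sorted(idx.terms)


class TestFrequenciesAndPriors:
    def test_full_and_half_coverage(self, chain_dag):
        records = [(f"P{i}", "T:a", "EXP") for i in range(10)]
        records += [(f"P{i}", "T:b", "EXP") for i in range(5)]
        ann = AnnotationTable.from_records(records, propagated=True)
        idx = build_class_index(chain_dag, ann, "molecular_function")
        freq = class_frequencies(ann, idx)
        by_term = dict(zip(idx.terms, freq.frequencies))
        assert by_term["T:a"] == 1.0
        assert by_term["T:b"] == 0.5

    def test_matches_label_matrix_column_sums(self, random_dag):
        from pufun.datasets import build_label_matrix

        rng = np.random.default_rng(3)
        ann = propagate_annotations(random_dag, random_annotations(random_dag, 30, rng))
        idx = build_class_index(random_dag, ann, "molecular_function")
        freq = class_frequencies(ann, idx)
        lm = build_label_matrix(ann, idx, ann.proteins)
        np.testing.assert_array_equal(freq.counts, lm.values.sum(axis=0))

    def test_prior_formula_and_scaling(self):
        freq = FrequencyVector(counts=np.array([10, 5, 1]), n_total=10)
        priors = compute_priors(freq, pi_o=1e-3, gamma=0.1)
        np.testing.assert_allclose(priors.pi, [1e-3, 5e-4, 1e-4])
        np.testing.assert_allclose(priors.beta, 0.1 * priors.pi)
        assert priors.pi.max() == pytest.approx(priors.pi_o)

    def test_single_class_attains_pi_o(self):
        freq = FrequencyVector(counts=np.array([4]), n_total=9)
        priors = compute_priors(freq, pi_o=0.05, gamma=0.0)
        np.testing.assert_allclose(priors.pi, [0.05])

    def test_prior_order_follows_frequency_order(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 50, size=20)
        freq = FrequencyVector(counts=counts, n_total=50)
        priors = compute_priors(freq, pi_o=1e-3, gamma=0.5)
        assert np.array_equal(np.argsort(priors.pi, kind="stable"),
                              np.argsort(freq.frequencies, kind="stable"))


class TestInformationContent:
    def test_root_certainty_gives_zero(self, chain_dag):
        ann = AnnotationTable.from_records(
            [(f"P{i}", "T:a", "EXP") for i in range(7)], propagated=True
        )
        idx = build_class_index(chain_dag, ann, "molecular_function")
        ic = information_content(chain_dag, ann, idx)
        assert ic.values[0] == pytest.approx(0.0)

    def test_half_conditional_probability(self, chain_dag):
        records = [(f"P{i}", "T:a", "EXP") for i in range(10)]
        records += [(f"P{i}", "T:b", "EXP") for i in range(5)]
        ann = AnnotationTable.from_records(records, propagated=True)
        idx = build_class_index(chain_dag, ann, "molecular_function")
        ic = information_content(chain_dag, ann, idx)
        by_term = dict(zip(idx.terms, ic.values))
        assert by_term["T:b"] == pytest.approx(-math.log(0.5))

    def test_matches_intersection_oracle(self, random_dag):
        rng = np.random.default_rng(31)
        ann = propagate_annotations(random_dag, random_annotations(random_dag, 35, rng))
        idx = build_class_index(random_dag, ann, "molecular_function")
        ic = information_content(random_dag, ann, idx)
        edges = propagation_edges(random_dag)
        pt = ann.protein_terms()
        for term, value in zip(idx.terms, ic.values):
            assert value == pytest.approx(ic_by_intersection(edges, pt, term), abs=1e-12)
            assert value >= 0.0
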