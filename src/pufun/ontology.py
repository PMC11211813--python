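"""Gene Ontology handling: OBO parsing, true-path-rule propagation, class
priors and information content.

The ontology is modelled as a DAG over term accessions with typed parent
edges (``is_a`` and, by default, ``part_of``).  A protein annotated to a term
is implicitly annotated to every ancestor of that term within the same
namespace (the true-path rule); propagated annotation frequencies drive both
the per-class priors used by the PU risk and the information content used by
the Smin metric.
"""

from __future__ import annotations

import io
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: relations followed when propagating annotations upward (standard GO practice)
DEFAULT_PROPAGATION_RELATIONS = ("is_a", "part_of")

#: experimental / curated evidence codes retained for training data
EXPERIMENTAL_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
     "HTP", "HDA", "HMP", "HGI", "HEP"}
)


class OboParseError(ValueError):
    """Raised when an OBO document cannot be parsed or is cyclic."""


@dataclass
class OntologyDAG:
    """Directed acyclic graph of ontology terms.

    Parameters
    ----------
    parents
        Map ``term -> {(parent, relation), ...}`` over canonical,
        non-obsolete terms.  Only relations listed in ``relations`` are
        followed for propagation, and only within the term's namespace.
    namespace
        Map ``term -> namespace`` for every canonical term.
    obsolete
        Accessions flagged obsolete; they carry no propagation edges.
    alt_ids
        Map ``secondary accession -> canonical accession``.
    relations
        Relation labels used for propagation.
    """

    parents: dict[str, set[tuple[str, str]]]
    namespace: dict[str, str]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    relations: tuple[str, ...] = DEFAULT_PROPAGATION_RELATIONS

    def __post_init__(self) -> None:
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- basic queries -----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        """All canonical term accessions (including obsolete ones)."""
        return set(self.namespace)

    def resolve(self, accession: str) -> str:
        """Map an accession through the alt_id table to its canonical form."""
        acc = self.alt_ids.get(accession, accession)
        if acc not in self.namespace:
            raise KeyError(f"unknown term accession: {accession!r}")
        return acc

    def propagation_parents(self, term: str) -> set[str]:
        """Parents reachable by one propagation edge, within the namespace."""
        if term in self.obsolete:
            return set()
        ns = self.namespace[term]
        return {
            p
            for p, rel in self.parents.get(term, ())
            if rel in self.relations
            and p not in self.obsolete
            and self.namespace.get(p) == ns
        }

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by repeatedly following propagation edges.

        The term itself is excluded.  Raises ``KeyError`` for unknown
        accessions and ``ValueError`` for obsolete ones.
        """
        acc = self.resolve(term)
        if acc in self.obsolete:
            raise ValueError(f"obsolete term has no ancestors: {term!r}")
        return set(self._ancestors_cached(acc))

    def _ancestors_cached(self, acc: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(acc)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.propagation_parents(acc):
            out.add(p)
            out |= self._ancestors_cached(p)
        result = frozenset(out)
        self._ancestor_cache[acc] = result
        return result

    def roots(self, namespace: str | None = None) -> set[str]:
        """Non-obsolete terms with no propagation parents."""
        return {
            t
            for t, ns in self.namespace.items()
            if t not in self.obsolete
            and (namespace is None or ns == namespace)
            and not self.propagation_parents(t)
        }

    def children_map(self) -> dict[str, set[str]]:
        """Inverse of the propagation edges: parent -> set of children."""
        out: dict[str, set[str]] = {t: set() for t in self.namespace}
        for t in self.namespace:
            if t in self.obsolete:
                continue
            for p in self.propagation_parents(t):
                out[p].add(t)
        return out

    # -- validation --------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(t for t in self.namespace if t not in self.obsolete)
        for t in self.namespace:
            if t in self.obsolete:
                continue
            for p, rel in self.parents.get(t, ()):
                if rel in self.relations and p not in self.obsolete:
                    g.add_edge(t, p)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise OboParseError(
                f"ontology propagation graph is cyclic (e.g. through {member!r})"
            )


# ---------------------------------------------------------------------------
# OBO reading / writing


def _validate_obo_lines(lines: list[str]) -> None:
    in_stanza = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("!", 1)[0].rstrip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise OboParseError(f"malformed stanza header at line {lineno}: {raw!r}")
            in_stanza = True
            continue
        if ":" not in line:
            where = "stanza" if in_stanza else "header"
            raise OboParseError(f"unparseable {where} line {lineno}: {raw!r}")


def parse_obo(
    source,
    relations: tuple[str, ...] = DEFAULT_PROPAGATION_RELATIONS,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 document into an :class:`OntologyDAG`.

    ``source`` may be a path, an open text handle, or the document itself as
    a string.  Obsolete terms are kept but flagged and excluded from
    propagation; ``alt_id`` lines populate the accession-resolution map.
    A cyclic ``is_a``/``part_of`` graph raises :class:`OboParseError` naming
    one cycle member.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    _validate_obo_lines(text.splitlines())

    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    default_ns = graph.graph.get("default-namespace", ["molecular_function"])
    if isinstance(default_ns, list):
        default_ns = default_ns[0]

    parents: dict[str, set[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}

    for term, data in graph.nodes(data=True):
        namespace[term] = data.get("namespace", default_ns)
        if data.get("name"):
            names[term] = data["name"]
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    # obonet stores edges child -> parent keyed by relation label
    for child, parent, rel in graph.edges(keys=True):
        if child in obsolete:
            continue
        parents.setdefault(child, set()).add((parent, rel))

    for alt, canon in alt_ids.items():
        if canon not in namespace:  # pragma: no cover - defensive
            raise OboParseError(f"alt_id {alt!r} points at unknown term {canon!r}")

    return OntologyDAG(
        parents=parents,
        namespace=namespace,
        obsolete=obsolete,
        alt_ids=alt_ids,
        names=names,
        relations=relations,
    )


def serialize_obo(dag: OntologyDAG) -> str:
    """Render a DAG back to OBO text (inverse of :func:`parse_obo`)."""
    chunks = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(dag.namespace):
        lines = [f"[Term]", f"id: {term}"]
        lines.append(f"name: {dag.names.get(term, term)}")
        lines.append(f"namespace: {dag.namespace[term]}")
        for alt, canon in sorted(dag.alt_ids.items()):
            if canon == term:
                lines.append(f"alt_id: {alt}")
        if term in dag.obsolete:
            lines.append("is_obsolete: true")
        else:
            for parent, rel in sorted(dag.parents.get(term, ())):
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
        chunks.append("\n".join(lines))
        chunks.append("")
    return "\n".join(chunks)


# ---------------------------------------------------------------------------
# Annotations


@dataclass
class AnnotationTable:
    """Rows of (protein, term, evidence code), optionally propagated.

    When ``propagated`` is true the table is upward-closed: a term's presence
    implies the presence of all its same-namespace ancestors.
    """

    df: pd.DataFrame
    propagated: bool = False

    COLUMNS = ("protein", "term", "evidence")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]], propagated: bool = False
    ) -> "AnnotationTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df, propagated=propagated)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.df["protein"].unique())

    def protein_terms(self) -> dict[str, set[str]]:
        """View of the table as protein -> set of term accessions."""
        out: dict[str, set[str]] = {}
        for prot, term in zip(self.df["protein"], self.df["term"]):
            out.setdefault(prot, set()).add(term)
        return out

    def restrict_proteins(self, proteins: Iterable[str]) -> "AnnotationTable":
        keep = set(proteins)
        return AnnotationTable(
            self.df[self.df["protein"].isin(keep)].reset_index(drop=True),
            propagated=self.propagated,
        )


def read_annotations_tsv(path) -> AnnotationTable:
    """Read a 3-column protein/term/evidence TSV (no header)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=list(AnnotationTable.COLUMNS), dtype=str,
        comment="!",
    )
    return AnnotationTable(df)


def read_gaf(path) -> AnnotationTable:
    """Read a GAF 2.x file: column 2 = protein, 5 = term, 7 = evidence."""
    df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    if df.shape[1] < 7:
        raise ValueError("GAF file has fewer than 7 columns")
    out = df.iloc[:, [1, 4, 6]].copy()
    out.columns = list(AnnotationTable.COLUMNS)
    return AnnotationTable(out)


def write_annotations_tsv(ann: AnnotationTable, path) -> None:
    ann.df.to_csv(path, sep="\t", header=False, index=False)


def resolve_annotations(dag: OntologyDAG, ann: AnnotationTable) -> AnnotationTable:
    """Map alt_ids to canonical accessions and drop obsolete-term rows.

    Unresolvable accessions raise ``KeyError`` listing every offender;
    dropped obsolete annotations emit a warning.
    """
    terms = ann.df["term"]
    mapped = terms.map(lambda t: dag.alt_ids.get(t, t))
    unknown = sorted(set(mapped) - dag.terms)
    if unknown:
        raise KeyError(f"unresolvable term accessions: {unknown}")
    df = ann.df.copy()
    df["term"] = mapped
    is_obs = df["term"].isin(dag.obsolete)
    if is_obs.any():
        warnings.warn(
            f"dropping {int(is_obs.sum())} annotation(s) to obsolete terms",
            stacklevel=2,
        )
        df = df[~is_obs]
    return AnnotationTable(df.reset_index(drop=True), propagated=ann.propagated)


def propagate_annotations(dag: OntologyDAG, ann: AnnotationTable) -> AnnotationTable:
    """Close an annotation table upward under the true-path rule.

    Each (protein, term) row contributes the term plus all of its ancestors
    within the term's namespace; added rows inherit the evidence code of the
    row they came from.  The operation is idempotent and preserves direct
    annotations.
    """
    ann = resolve_annotations(dag, ann)
    records: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for prot, term, ev in ann.df.itertuples(index=False):
        for t in (term, *sorted(dag.ancestors(term))):
            key = (prot, t)
            if key not in seen:
                seen.add(key)
                records.append((prot, t, ev))
    return AnnotationTable.from_records(records, propagated=True)


# ---------------------------------------------------------------------------
# Class index, frequencies, priors, information content


@dataclass
class ClassIndex:
    """Deterministic term-to-column mapping for one namespace."""

    namespace: str
    terms: list[str]
    min_count: int = 1

    def __post_init__(self) -> None:
        self.position = {t: i for i, t in enumerate(self.terms)}
        if len(self.position) != len(self.terms):
            raise ValueError("duplicate terms in class index")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.position


@dataclass
class FrequencyVector:
    """Per-class annotated-protein counts and frequencies S_i = N_i/N_total."""

    counts: np.ndarray  # integer N_i per indexed class
    n_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_total <= 0:
            raise ValueError("N_total must be positive")
        if np.any(self.counts <= 0) or np.any(self.counts > self.n_total):
            raise ValueError("class counts must satisfy 0 < N_i <= N_total")
        self.frequencies = self.counts / self.n_total
        self.s_max = float(self.frequencies.max())


@dataclass
class PriorVector:
    """Per-class priors pi_i scaled from annotation frequency.

    pi_i = pi_o * S_i / S_max, so the most frequent class attains the base
    prior pi_o exactly.  The clamp offset of the non-negative risk is
    beta_i = gamma * pi_i, which keeps 0 <= beta_i <= pi_i per class.
    """

    pi: np.ndarray
    pi_o: float
    gamma: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not 0.0 < self.pi_o < 1.0:
            raise ValueError("pi_o must lie in (0, 1)")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if np.any(self.pi <= 0) or np.any(self.pi > self.pi_o + 1e-12):
            raise ValueError("priors must satisfy 0 < pi_i <= pi_o")

    @property
    def beta(self) -> np.ndarray:
        return self.gamma * self.pi

    @classmethod
    def uniform(cls, k: int, pi_o: float, gamma: float) -> "PriorVector":
        return cls(np.full(k, pi_o), pi_o=pi_o, gamma=gamma)


@dataclass
class ICVector:
    """Per-class information content, natural log, IC(c) >= 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < -1e-12):
            raise ValueError("information content must be finite and non-negative")
        self.values = np.maximum(self.values, 0.0)


def build_class_index(
    dag: OntologyDAG,
    ann: AnnotationTable,
    namespace: str,
    min_count: int = 1,
) -> ClassIndex:
    """Select the namespace's terms with >= min_count annotated proteins.

    Requires a propagated table so that counts respect the true-path rule.
    Terms are ordered lexicographically, making the index deterministic.
    """
    if not ann.propagated:
        raise ValueError("class index must be built from a propagated table")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = (
        ann.df[ann.df["term"].map(lambda t: dag.namespace.get(t)) == namespace]
        .groupby("term")["protein"]
        .nunique()
    )
    terms = sorted(counts.index[counts >= min_count])
    if not terms:
        raise ValueError(
            f"empty vocabulary for namespace {namespace!r} at min_count={min_count}"
        )
    return ClassIndex(namespace=namespace, terms=terms, min_count=min_count)


def class_frequencies(ann: AnnotationTable, index: ClassIndex) -> FrequencyVector:
    """Count distinct annotated training proteins per indexed class."""
    if not ann.propagated:
        raise ValueError("frequencies require a propagated table")
    n_total = ann.df["protein"].nunique()
    by_term = ann.df.groupby("term")["protein"].nunique()
    counts = np.array([int(by_term.get(t, 0)) for t in index.terms])
    if np.any(counts == 0):
        zero = [t for t, c in zip(index.terms, counts) if c == 0]
        raise ValueError(
            f"indexed classes with zero training annotations: {zero[:5]} "
            "(vocabulary and frequencies must come from the same table)"
        )
    return FrequencyVector(counts=counts, n_total=n_total)


def compute_priors(freq: FrequencyVector, pi_o: float, gamma: float) -> PriorVector:
    """pi_i = pi_o * S_i / S_max; records beta_i = gamma * pi_i."""
    pi = pi_o * freq.frequencies / freq.s_max
    return PriorVector(pi=pi, pi_o=pi_o, gamma=gamma)


def information_content(
    dag: OntologyDAG, ann: AnnotationTable, index: ClassIndex
) -> ICVector:
    """IC(c) = -ln Pr(c | P(c)) from propagated training annotations.

    Pr(c | P(c)) = N_c / N_{P(c)}, where N_{P(c)} counts training proteins
    annotated with *every* propagation parent of c; for a root the
    denominator is the whole training set.  Propagation guarantees
    N_c <= N_{P(c)}, hence IC >= 0, with IC(root) = 0 when the root covers
    the full set.
    """
    if not ann.propagated:
        raise ValueError("information content requires a propagated table")
    prot_terms = ann.protein_terms()
    n_total = len(prot_terms)
    term_count: dict[str, int] = {}
    for terms in prot_terms.values():
        for t in terms:
            term_count[t] = term_count.get(t, 0) + 1

    values = np.empty(len(index), dtype=float)
    for j, c in enumerate(index.terms):
        n_c = term_count.get(c, 0)
        parents = dag.propagation_parents(dag.resolve(c))
        if not parents:
            n_parent = n_total
        else:
            n_parent = sum(1 for ts in prot_terms.values() if parents <= ts)
        if n_parent == 0 or n_c == 0 or n_c > n_parent:
            raise ValueError(
                f"inconsistent counts for {c!r}: N_c={n_c}, N_parents={n_parent} "
                "(table must be propagated and cover the index)"
            )
        values[j] = -math.log(n_c / n_parent)
    return ICVector(values=values)


def write_values_tsv(index: ClassIndex, values: np.ndarray, path) -> None:
    """Export per-class values (priors, IC, ...) as a term/value TSV."""
    pd.DataFrame({"term": index.terms, "value": np.asarray(values)}).to_csv(
        path, sep="\t", header=False, index=False
    )
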