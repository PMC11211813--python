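"""Dataset construction: evidence filtering, similarity-graph grouping,
group-respecting splits, and label-matrix assembly.

Sequence-similar proteins leak information across train/test boundaries, so
splitting operates on connected components of the pairwise similarity graph
(DIAMOND/BLAST hits at e-value <= 0.001): every member of a component shares
one split, guaranteeing no retained hit crosses a boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import (
    AnnotationTable,
    ClassIndex,
    EXPERIMENTAL_EVIDENCE_CODES,
)

DEFAULT_EVALUE_MAX = 0.001
DEFAULT_SPLIT_FRACTIONS = (0.81, 0.09, 0.10)
SPLIT_NAMES = ("train", "valid", "test")


@dataclass
class SimilarityHits:
    """Tabular pairwise similarity hits (query, subject, e-value, bitscore)."""

    df: pd.DataFrame

    COLUMNS = ("query", "subject", "evalue", "bitscore")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"similarity hits missing columns: {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.df["evalue"] < 0).any():
            raise ValueError("e-values must be non-negative")
        if (self.df["bitscore"] <= 0).any():
            raise ValueError("bitscores must be positive")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "SimilarityHits":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))


def read_blast_tab(
    path,
    query_col: int = 0,
    subject_col: int = 1,
    evalue_col: int = 10,
    bitscore_col: int = 11,
) -> SimilarityHits:
    """Read BLAST/DIAMOND tabular output (outfmt 6 by default).

    Column positions are configurable for non-standard outfmt layouts.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, [query_col, subject_col, evalue_col, bitscore_col]].copy()
    out.columns = list(SimilarityHits.COLUMNS)
    out["query"] = out["query"].astype(str)
    out["subject"] = out["subject"].astype(str)
    out["evalue"] = out["evalue"].astype(float)
    out["bitscore"] = out["bitscore"].astype(float)
    return SimilarityHits(out)


def read_fasta_ids(path) -> list[str]:
    """Extract record ids from a FASTA file (sequences are not used)."""
    from Bio import SeqIO

    return [rec.id for rec in SeqIO.parse(str(path), "fasta")]


@dataclass
class GroupAssignment:
    """Partition of proteins into similarity groups (connected components)."""

    protein_group: dict[str, int]

    def __post_init__(self) -> None:
        members: dict[int, list[str]] = {}
        for prot, g in self.protein_group.items():
            members.setdefault(g, []).append(prot)
        self.group_members = {g: sorted(ms) for g, ms in members.items()}

    @property
    def n_groups(self) -> int:
        return len(self.group_members)

    def __len__(self) -> int:
        return len(self.protein_group)


@dataclass
class SplitAssignment:
    """protein -> split label, produced group-at-a-time from a seed."""

    protein_split: dict[str, str]
    seed: int

    def proteins(self, split: str) -> list[str]:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return sorted(p for p, s in self.protein_split.items() if s == split)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.protein_split.items()), columns=["protein", "split"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_split_tsv(path, seed: int = -1) -> SplitAssignment:
    df = pd.read_csv(path, sep="\t", header=None, names=["protein", "split"], dtype=str)
    return SplitAssignment(dict(zip(df["protein"], df["split"])), seed=seed)


# ---------------------------------------------------------------------------


def filter_by_evidence(
    ann: AnnotationTable,
    codes: frozenset[str] | set[str] = EXPERIMENTAL_EVIDENCE_CODES,
) -> AnnotationTable:
    """Keep only rows with an accepted evidence code.

    Defaults to the 13 experimental/curated codes (EXP, IDA, IPI, IMP, IGI,
    IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP).  Proteins left with no rows
    simply disappear from the table.
    """
    keep = ann.df["evidence"].isin(set(codes))
    return AnnotationTable(ann.df[keep].reset_index(drop=True), propagated=ann.propagated)


def similarity_groups(
    hits: SimilarityHits,
    e_max: float = DEFAULT_EVALUE_MAX,
    proteins: Sequence[str] | None = None,
) -> GroupAssignment:
    """Group proteins by connected components of the retained-hit graph.

    A hit is retained when its e-value is <= ``e_max``; direction and
    self-hits are ignored (when duplicate hits disagree, retention by the
    lower e-value is equivalent to keeping the pair if *any* copy passes).
    ``proteins`` adds isolated vertices so annotation-only proteins become
    singleton groups.
    """
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    g = nx.Graph()
    if proteins is not None:
        g.add_nodes_from(proteins)
    df = hits.df
    g.add_nodes_from(df["query"])
    g.add_nodes_from(df["subject"])
    kept = df[df["evalue"] <= e_max]
    for q, s in zip(kept["query"], kept["subject"]):
        if q != s:
            g.add_edge(q, s)
    protein_group: dict[str, int] = {}
    # sort components by their smallest member for deterministic ids
    comps = sorted(nx.connected_components(g), key=min)
    for gid, comp in enumerate(comps):
        for prot in comp:
            protein_group[prot] = gid
    return GroupAssignment(protein_group)


def split_groups(
    groups: GroupAssignment,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole similarity groups to train/valid/test.

    Implemented as the two-stage procedure the fractions describe: a
    test share of the groups is held out first, then the validation share is
    carved out of the remaining training groups (0.81/0.09/0.10 arises from
    90/10 followed by 10% of training).  Deterministic given the seed;
    proportions hold at the *group* level, so protein-level percentages
    drift with group sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = groups.n_groups
    if n < 3:
        raise ValueError(f"need at least 3 groups to split, got {n}")
    f_train, f_valid, f_test = fractions
    rng = np.random.default_rng(seed)
    gids = sorted(groups.group_members)
    order = rng.permutation(n)
    n_test = int(round(n * f_test))
    n_valid = int(round((n - n_test) * f_valid / (f_train + f_valid)))
    n_test = min(max(n_test, 1), n - 2)
    n_valid = min(max(n_valid, 1), n - n_test - 1)
    test_ids = {gids[i] for i in order[:n_test]}
    valid_ids = {gids[i] for i in order[n_test : n_test + n_valid]}

    protein_split: dict[str, str] = {}
    for gid, members in groups.group_members.items():
        split = "test" if gid in test_ids else "valid" if gid in valid_ids else "train"
        for prot in members:
            protein_split[prot] = split

    sizes = {g: len(m) for g, m in groups.group_members.items()}
    total = sum(sizes.values())
    biggest = max(sizes.values())
    if total and biggest / total >= 0.5:
        warnings.warn(
            f"a single similarity group holds {biggest}/{total} proteins; "
            "most of the dataset lands in one split",
            stacklevel=2,
        )
    return SplitAssignment(protein_split, seed=seed)


@dataclass
class LabelMatrix:
    """proteins x classes binary matrix with PU semantics.

    A 1 marks a labeled positive; a 0 marks an *unlabeled* cell, not a
    negative.  Rows follow ``proteins``; columns follow ``index``.
    """

    proteins: list[str]
    index: ClassIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.proteins), len(self.index)):
            raise ValueError("label matrix shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_label_matrix(
    ann: AnnotationTable,
    index: ClassIndex,
    proteins: Sequence[str],
) -> LabelMatrix:
    """Assemble the binary label matrix for an ordered protein list.

    Proteins without any indexed term yield all-zero rows (fully unlabeled).
    """
    if not ann.propagated:
        raise ValueError("label matrix requires a propagated table")
    prot_terms = ann.protein_terms()
    y = np.zeros((len(proteins), len(index)), dtype=np.int8)
    for i, prot in enumerate(proteins):
        for term in prot_terms.get(prot, ()):
            j = index.position.get(term)
            if j is not None:
                y[i, j] = 1
    return LabelMatrix(proteins=list(proteins), index=index, values=y)
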