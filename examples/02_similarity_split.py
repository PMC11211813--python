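"""Group proteins by sequence similarity and split without leakage.

Builds a small DIAMOND-style hit table, forms connected-component groups
at e-value <= 0.001, splits the groups ~81/9/10, and verifies that no
retained hit connects two different splits.
"""

from pufun import SimilarityHits, similarity_groups, split_groups

hits = SimilarityHits.from_records([
    ("A", "B", 1e-50, 280.0),   # A-B-C form one homologous family
    ("B", "C", 1e-30, 150.0),
    ("D", "E", 1e-10, 90.0),    # D-E a second family
    ("F", "G", 0.05, 45.0),     # too weak: F and G stay singletons
])
proteins = list("ABCDEFGHIJ")   # H, I, J have no hits at all

groups = similarity_groups(hits, e_max=0.001, proteins=proteins)
print(f"{groups.n_groups} groups over {len(proteins)} proteins:")
for gid, members in sorted(groups.group_members.items()):
    print(f"  group {gid}: {members}")

split = split_groups(groups, seed=11)
for name in ("train", "valid", "test"):
    print(f"{name}: {split.proteins(name)}")

leaks = sum(
    split.protein_split[q] != split.protein_split[s]
    for q, s, ev, _ in hits.df.itertuples(index=False)
    if ev <= 0.001
)
print(f"retained hits crossing split boundaries: {leaks}")
# Always 0: whole similarity families move between splits as units.
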