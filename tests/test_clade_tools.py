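import pytest

from symgras.clade_tools import (
    CladeCutoff,
    CladeDefinition,
    basalmost_members,
    derive_cutoff,
    leaf_labels,
    merge_clades,
    mrca,
    nearest_outside_clade,
    parse_tree,
    read_clades_tsv,
    read_cutoffs_tsv,
    read_tree,
    root_by_outgroup,
    tree_to_newick,
    write_clades_tsv,
    write_cutoffs_tsv,
)
from symgras.classify import ScoreTable
from symgras.errors import ArgumentError, DataError
from symgras.profile_hmm import ScoreRecord


def bipartitions(tree):
    t = tree.clone(depth=1)
    t.encode_bipartitions()
    return {b.leafset_bitmask for b in t.bipartition_encoding}


def test_root_by_outgroup_quartet():
    tree = parse_tree("((A,B),(GAI,RGA));", rooted=False)
    rooted = root_by_outgroup(tree, {"GAI", "RGA"})
    sides = [
        {l.taxon.label for l in c.leaf_iter()}
        for c in rooted.seed_node.child_nodes()
    ]
    assert {"GAI", "RGA"} in sides
    assert {"A", "B"} in sides


def test_root_by_outgroup_identity_on_already_rooted():
    tree = parse_tree("((A,(B,C)),(GAI,RGA));")
    rooted = root_by_outgroup(tree, {"GAI", "RGA"})
    assert bipartitions(rooted) == bipartitions(tree)
    assert sorted(leaf_labels(rooted)) == sorted(leaf_labels(tree))


def test_root_by_outgroup_errors():
    tree = parse_tree("((A,GAI),(B,RGA));")
    with pytest.raises(ArgumentError, match="not separable"):
        root_by_outgroup(tree, {"GAI", "RGA"})
    with pytest.raises(ArgumentError, match="absent"):
        root_by_outgroup(tree, {"GAI", "NOPE"})


def test_mrca_cases():
    tree = parse_tree("(((A,B),C),D);")
    assert {l.taxon.label for l in mrca(tree, ["A", "B", "C", "D"]).leaf_iter()} == {
        "A", "B", "C", "D",
    }
    assert mrca(tree, ["A"]).taxon.label == "A"
    assert {l.taxon.label for l in mrca(tree, ["A", "C"]).leaf_iter()} == {"A", "B", "C"}
    with pytest.raises(ArgumentError):
        mrca(tree, ["A", "MISSING"])


def test_basalmost_members_smaller_child():
    tree = parse_tree("(((a,b),(c,(d,e))),out);")
    clade = CladeDefinition("NSP1", frozenset("abcde"))
    assert basalmost_members(tree, clade) == {"a", "b"}


def test_basalmost_members_pair_and_tie():
    tree = parse_tree("((a,b),out);")
    assert basalmost_members(tree, CladeDefinition("NSP1", frozenset("ab"))) == {"a", "b"}
    tree4 = parse_tree("(((a,b),(c,d)),out);")
    assert basalmost_members(tree4, CladeDefinition("NSP1", frozenset("abcd"))) == {
        "a", "b", "c", "d",
    }


def test_nearest_outside_clade():
    tree = parse_tree("(((NSP1a,NSP1b),NSP2x),out);")
    clade = CladeDefinition("NSP1", frozenset({"NSP1a", "NSP1b"}))
    assert nearest_outside_clade(tree, clade) == {"NSP2x"}
    assert nearest_outside_clade(tree, clade, exclude=()) == {"NSP2x"}
    whole = CladeDefinition("NSP1", frozenset({"NSP1a", "NSP1b", "NSP2x", "out"}))
    with pytest.raises(ArgumentError, match="root"):
        nearest_outside_clade(tree, whole)


def scores_for(mapping, model="NSP1"):
    return ScoreTable.from_records(
        [ScoreRecord(sid, model, bits) for sid, bits in mapping.items()]
    )


def test_derive_cutoff_midpoint_and_flags():
    tree = parse_tree("(((a,b),(c,(d,e))),(x,y));")
    clade = CladeDefinition("NSP1", frozenset("abcde"))
    # basalmost = {a,b}; nearest outside = {x,y}
    table = scores_for({"a": 120, "b": 150, "c": 140, "d": 130, "e": 135, "x": 80, "y": 60})
    cutoff = derive_cutoff(table, tree, clade)
    assert cutoff.cutoff_bits == pytest.approx(100.0)
    assert cutoff.in_clade_basal_min == 120
    assert cutoff.out_clade_max == 80
    assert not cutoff.overlap_flag

    overlap = scores_for({"a": 80, "b": 90, "c": 140, "d": 130, "e": 135, "x": 120, "y": 60})
    c2 = derive_cutoff(overlap, tree, clade)
    assert c2.cutoff_bits == pytest.approx(100.0)
    assert c2.overlap_flag


def test_derive_cutoff_row_permutation_invariant():
    tree = parse_tree("(((a,b),(c,(d,e))),(x,y));")
    clade = CladeDefinition("NSP1", frozenset("abcde"))
    vals = {"a": 120, "b": 150, "c": 140, "d": 130, "e": 135, "x": 80, "y": 60}
    c1 = derive_cutoff(scores_for(vals), tree, clade)
    rev = dict(reversed(list(vals.items())))
    c2 = derive_cutoff(scores_for(rev), tree, clade)
    assert c1 == c2


def test_derive_cutoff_missing_scores_listed():
    tree = parse_tree("(((a,b),c),(x,y));")
    clade = CladeDefinition("NSP1", frozenset("abc"))
    table = scores_for({"a": 120, "b": 90, "c": 100, "x": 10})  # y missing
    with pytest.raises(DataError, match="y"):
        derive_cutoff(table, tree, clade)


def test_merge_clades_uses_configured_order():
    a = CladeDefinition("RAD1", frozenset({"r1"}))
    b = CladeDefinition("RAM1", frozenset({"m1"}))
    merged = merge_clades(a, b)
    assert merged.subfamily == "RAM1+RAD1"
    assert merged.member_ids == {"r1", "m1"}
    assert CladeCutoff("RAM1+RAD1", 1.0, 2.0, 0.0, False).components == ("RAM1", "RAD1")


def test_newick_quoted_labels_and_comments(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((‘A_1’,B)[&support=99],(C,D));".replace("‘", "'").replace("’", "'"))
    tree = read_tree(p)
    assert "A_1" in leaf_labels(tree)
    out = tmp_path / "out.nwk"
    out.write_text(tree_to_newick(tree))
    assert "A_1" in leaf_labels(read_tree(out))


def test_clades_and_cutoffs_tsv_roundtrip(tmp_path):
    clades = [
        CladeDefinition("NSP1", frozenset({"a", "b"})),
        CladeDefinition("NSP2", frozenset({"c"})),
    ]
    p = tmp_path / "clades.tsv"
    write_clades_tsv(clades, p)
    assert read_clades_tsv(p) == clades

    cutoffs = [
        CladeCutoff("NSP1", 100.0, 120.0, 80.0, False),
        CladeCutoff("RAM1+RAD1", 90.0, 85.0, 95.0, True),
    ]
    q = tmp_path / "cutoffs.tsv"
    write_cutoffs_tsv(cutoffs, q)
    assert read_cutoffs_tsv(q) == cutoffs
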