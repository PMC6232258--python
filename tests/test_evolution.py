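import numpy as np
import pytest

from oracles import brute_force_sankoff
from conftest import BRYOPHYTE_SPECIES, SUBFAMS

from symgras.clade_tools import parse_tree
from symgras.classify import Assignment
from symgras.errors import DataError
from symgras.evolution import (
    TRANSCRIPTOME,
    CopyNumberMatrix,
    build_copy_matrix,
    copy_number_parsimony,
    dollo_reconstruct,
    event_report,
    reconstruct_events,
)
from symgras.synthetic_data import simulate_species_tree


def assignment(sid, fam, species=None):
    return Assignment(sid, species or sid[:5], fam, 150.0, 10.0, False)


# ---------------------------------------------------------------------------
# copy matrix
# ---------------------------------------------------------------------------

def test_build_copy_matrix_takakia_complement():
    tree = parse_tree("((TAKLE,SPHFA),MARPO);")
    assignments = (
        [assignment(f"TAKLE_{i}", "NSP1") for i in (1, 2)]
        + [assignment("TAKLE_3", "NSP2")]
        + [assignment(f"TAKLE_{i}", "RAM1") for i in (4, 5)]
        + [assignment(f"TAKLE_{i}", "RAD1") for i in (6, 7, 8)]
    )
    matrix = build_copy_matrix(assignments, tree)
    assert [matrix.count("TAKLE", f) for f in SUBFAMS] == [2, 1, 2, 3]
    # species with no assignments get all-zero rows
    assert [matrix.count("SPHFA", f) for f in SUBFAMS] == [0, 0, 0, 0]
    assert matrix.subfamilies == list(SUBFAMS)


def test_build_copy_matrix_unknown_species_is_error():
    tree = parse_tree("(TAKLE,MARPO);")
    with pytest.raises(DataError, match="PHYPA"):
        build_copy_matrix([assignment("PHYPA_1", "NSP1")], tree)


def test_copy_matrix_column_order_is_configured_not_observed():
    tree = parse_tree("(TAKLE,MARPO);")
    assignments = [assignment("MARPO_1", "RAD1"), assignment("TAKLE_1", "NSP1")]
    matrix = build_copy_matrix(assignments, tree)
    assert matrix.subfamilies == list(SUBFAMS)


# ---------------------------------------------------------------------------
# Dollo
# ---------------------------------------------------------------------------

def test_dollo_fixture_six_losses_exact_placement(bryophyte_tree, bryophyte_matrix):
    recon = dollo_reconstruct(bryophyte_matrix, bryophyte_tree)
    losses = {(e.subfamily, e.branch) for e in recon.branch_events}
    # N4 labels the Sphagnum+Bryophytina stem on this topology
    assert losses == {
        ("NSP2", "hornworts"), ("NSP2", "N4"),
        ("RAM1", "liverworts"), ("RAM1", "N4"),
        ("RAD1", "hornworts"), ("RAD1", "N4"),
    }
    assert recon.total_cost == 6
    assert all(e.event == "loss" for e in recon.branch_events)
    # leaf states equal the observed presence/absence
    for i, sp in enumerate(BRYOPHYTE_SPECIES):
        for j, fam in enumerate(SUBFAMS):
            assert recon.ancestral_states[sp][fam] == int(
                bryophyte_matrix.counts[i, j] > 0
            )


def test_dollo_all_present_no_events(bryophyte_tree):
    matrix = CopyNumberMatrix(BRYOPHYTE_SPECIES, list(SUBFAMS), np.ones((5, 4), int))
    recon = dollo_reconstruct(matrix, bryophyte_tree)
    assert recon.branch_events == [] and recon.total_cost == 0


def test_dollo_single_absent_leaf_terminal_loss(bryophyte_tree):
    counts = np.ones((5, 4), int)
    counts[BRYOPHYTE_SPECIES.index("Sphagnum"), 0] = 0
    matrix = CopyNumberMatrix(BRYOPHYTE_SPECIES, list(SUBFAMS), counts)
    recon = dollo_reconstruct(matrix, bryophyte_tree)
    assert [(e.subfamily, e.branch, e.event) for e in recon.branch_events] == [
        ("NSP1", "Sphagnum", "loss")
    ]


def test_dollo_losses_bounded_by_absent_leaves():
    rng = np.random.default_rng(17)
    for rep in range(30):
        tree = simulate_species_tree(7, int(rng.integers(2**31 - 1)))
        counts = rng.integers(0, 3, size=(7, 4))
        species = [l.taxon.label for l in tree.leaf_node_iter()]
        matrix = CopyNumberMatrix(species, list(SUBFAMS), counts)
        recon = dollo_reconstruct(matrix, tree)
        for j, fam in enumerate(SUBFAMS):
            n_losses = sum(1 for e in recon.branch_events if e.subfamily == fam)
            assert n_losses <= int((counts[:, j] == 0).sum())


def test_dollo_soft_absence_marginalized(bryophyte_tree, bryophyte_matrix):
    ev = np.array(bryophyte_matrix.evidence, dtype=object)
    ev[BRYOPHYTE_SPECIES.index("hornworts"), :] = TRANSCRIPTOME
    matrix = CopyNumberMatrix(
        BRYOPHYTE_SPECIES, list(SUBFAMS), bryophyte_matrix.counts, ev
    )
    recon = dollo_reconstruct(
        matrix, bryophyte_tree, transcriptome_absence_as_missing=True
    )
    # hornwort absences (NSP2, RAD1) no longer justify terminal losses
    assert ("NSP2", "hornworts") not in {
        (e.subfamily, e.branch) for e in recon.branch_events
    }
    assert recon.total_cost == 4


def test_dollo_requires_rooted_tree(bryophyte_matrix):
    tree = parse_tree("(hornworts,(liverworts,(Takakia,(Sphagnum,Bryophytina))));")
    tree.is_rooted = False
    with pytest.raises(DataError, match="rooted"):
        dollo_reconstruct(bryophyte_matrix, tree)


# ---------------------------------------------------------------------------
# Sankoff copy-number parsimony
# ---------------------------------------------------------------------------

def test_sankoff_uniform_counts_no_events(bryophyte_tree):
    matrix = CopyNumberMatrix(BRYOPHYTE_SPECIES, list(SUBFAMS), np.ones((5, 4), int))
    recon = copy_number_parsimony(matrix, bryophyte_tree)
    assert recon.branch_events == [] and recon.total_cost == 0


def test_sankoff_flags_nsp1_expansion_on_bryophytina(bryophyte_tree, bryophyte_matrix):
    recon = copy_number_parsimony(bryophyte_matrix, bryophyte_tree)
    bryo = [
        e for e in recon.branch_events
        if e.subfamily == "NSP1" and e.branch == "Bryophytina"
    ]
    assert len(bryo) == 1
    assert bryo[0].event == "expansion" and bryo[0].copy_change > 0


def test_sankoff_max_count_violation_names_cell(bryophyte_tree, bryophyte_matrix):
    # the offending cell is the expanded NSP1 count in Bryophytina (4 > 3)
    with pytest.raises(DataError, match="Bryophytina.*NSP1"):
        copy_number_parsimony(bryophyte_matrix, bryophyte_tree, max_count=3)


def test_sankoff_matches_bruteforce_on_random_trees():
    rng = np.random.default_rng(23)
    for rep in range(12):
        n = int(rng.integers(4, 8))
        tree = simulate_species_tree(n, int(rng.integers(2**31 - 1)))
        species = [l.taxon.label for l in tree.leaf_node_iter()]
        counts = rng.integers(0, 5, size=(n, 2))
        matrix = CopyNumberMatrix(species, ["NSP1", "NSP2"], counts)
        recon = copy_number_parsimony(matrix, tree)
        expected = sum(
            brute_force_sankoff(
                tree, dict(zip(species, counts[:, j])), int(counts.max()) + 1
            )
            for j in range(2)
        )
        assert recon.total_cost == expected


def test_sankoff_projection_consistent_with_dollo():
    rng = np.random.default_rng(29)
    for rep in range(20):
        n = int(rng.integers(4, 9))
        tree = simulate_species_tree(n, int(rng.integers(2**31 - 1)))
        species = [l.taxon.label for l in tree.leaf_node_iter()]
        counts = rng.integers(0, 4, size=(n, 4))
        matrix = CopyNumberMatrix(species, list(SUBFAMS), counts)
        dollo = dollo_reconstruct(matrix, tree)
        sankoff = copy_number_parsimony(matrix, tree)
        for node, states in sankoff.ancestral_states.items():
            for fam, copies in states.items():
                assert (copies > 0) == (dollo.ancestral_states[node][fam] > 0)


def test_sankoff_counts_cooptimal_labelings():
    # a cherry with leaves 0 and 2: root may sit at 1 or 2 at equal cost
    tree = parse_tree("(A,B);")
    counts = np.array([[0], [2]])
    matrix = CopyNumberMatrix(["A", "B"], ["NSP1"], counts)
    recon = copy_number_parsimony(matrix, tree)
    assert recon.total_cost == 2
    assert recon.n_cooptimal == 2
    # deep-loss preference on a clean case: loss goes on the stem, not leaves
    tree2 = parse_tree("((A,B),(C,D));")
    m2 = CopyNumberMatrix(["A", "B", "C", "D"], ["NSP1"], np.array([[1], [1], [0], [0]]))
    r2 = copy_number_parsimony(m2, tree2)
    assert [e.branch for e in r2.branch_events] == ["N3"]
    assert r2.total_cost == 1 and r2.n_cooptimal == 1


# ---------------------------------------------------------------------------
# combined events + report
# ---------------------------------------------------------------------------

def test_event_report_fixture_lists_losses_and_expansion(bryophyte_tree, bryophyte_matrix):
    recon = reconstruct_events(bryophyte_matrix, bryophyte_tree)
    report = event_report(recon, bryophyte_matrix)
    text = report.to_text()
    losses = [e for e in recon.branch_events if e.event == "loss"]
    assert len(losses) == 6
    nsp1_bryo = [
        e for e in recon.branch_events
        if e.subfamily == "NSP1" and e.branch == "Bryophytina" and e.event == "expansion"
    ]
    assert len(nsp1_bryo) == 1
    assert "Bryophytina: NSP1 expansion" in text


def test_event_report_soft_absence_annotated(bryophyte_tree, bryophyte_matrix):
    ev = np.array(bryophyte_matrix.evidence, dtype=object)
    ev[BRYOPHYTE_SPECIES.index("liverworts"), :] = TRANSCRIPTOME
    matrix = CopyNumberMatrix(
        BRYOPHYTE_SPECIES, list(SUBFAMS), bryophyte_matrix.counts, ev
    )
    recon = reconstruct_events(matrix, bryophyte_tree)
    text = event_report(recon, matrix).to_text()
    assert "transcriptome-only; absence not conclusive" in text
    assert "liverworts: RAM1" in text


def test_event_report_empty_events(bryophyte_tree):
    matrix = CopyNumberMatrix(BRYOPHYTE_SPECIES, list(SUBFAMS), np.ones((5, 4), int))
    recon = reconstruct_events(matrix, bryophyte_tree)
    assert "no events inferred" in event_report(recon, matrix).to_text()
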