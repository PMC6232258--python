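import math

import numpy as np
import pytest

from symgras.clade_tools import CladeCutoff
from symgras.classify import (
    ScoreTable,
    UNASSIGNED,
    classify_sequences,
    species_complement,
)
from symgras.errors import ArgumentError, DataError
from symgras.profile_hmm import ScoreRecord

FAMS = ("NSP1", "NSP2", "RAM1", "RAD1")


def table_from(rows: dict[str, dict[str, float]]) -> ScoreTable:
    return ScoreTable.from_records(
        [
            ScoreRecord(sid, model, bits)
            for sid, models in rows.items()
            for model, bits in models.items()
        ]
    )


def flat_cutoffs(value=100.0):
    return [CladeCutoff(f, value, value + 20, value - 20, False) for f in FAMS]


def test_single_pass_assigns_without_ambiguity():
    table = table_from({"PHYPA_1": {"NSP1": 150, "NSP2": 40, "RAM1": 35, "RAD1": 30}})
    [a] = classify_sequences(table, flat_cutoffs())
    assert a.subfamily == "NSP1"
    assert a.best_score_bits == 150
    assert not a.ambiguous_flag
    assert math.isinf(a.margin_bits)


def test_decoy_below_all_cutoffs_is_unassigned():
    table = table_from({"PHYPA_d": {f: -5.0 for f in FAMS}})
    [a] = classify_sequences(table, flat_cutoffs())
    assert a.subfamily == UNASSIGNED
    assert a.margin_bits == 0.0 and not a.ambiguous_flag


def test_merged_cutoff_close_components_keep_merged_label():
    table = table_from(
        {"TAKLE_1": {"NSP1": 10, "NSP2": 10, "RAM1": 112, "RAD1": 111}}
    )
    cutoffs = [
        CladeCutoff("NSP1", 100, 120, 80, False),
        CladeCutoff("NSP2", 100, 120, 80, False),
        CladeCutoff("RAM1+RAD1", 100, 120, 80, False),
    ]
    [a] = classify_sequences(table, cutoffs, ambiguity_margin=2.0)
    assert a.subfamily == "RAM1+RAD1"
    assert a.ambiguous_flag


def test_merged_cutoff_clear_component_resolves():
    table = table_from(
        {"TAKLE_1": {"NSP1": 10, "NSP2": 10, "RAM1": 130, "RAD1": 105}}
    )
    cutoffs = [
        CladeCutoff("NSP1", 100, 120, 80, False),
        CladeCutoff("NSP2", 100, 120, 80, False),
        CladeCutoff("RAM1+RAD1", 100, 120, 80, False),
    ]
    [a] = classify_sequences(table, cutoffs)
    assert a.subfamily == "RAM1"
    assert not a.ambiguous_flag


def test_multi_pass_small_margin_flags_ambiguity():
    table = table_from({"MARPO_1": {"NSP1": 120, "NSP2": 119, "RAM1": 0, "RAD1": 0}})
    [a] = classify_sequences(table, flat_cutoffs())
    assert a.subfamily == "NSP1"
    assert a.margin_bits == pytest.approx(1.0)
    assert a.ambiguous_flag


def test_cutoff_without_scores_is_error():
    table = table_from({"MARPO_1": {"NSP1": 1.0}})
    with pytest.raises(DataError, match="NSP2"):
        classify_sequences(table, flat_cutoffs())


def test_every_sequence_gets_exactly_one_assignment():
    rng = np.random.default_rng(5)
    rows = {
        f"SP{chr(65+i)}{chr(65+j)}X_{i}_{j}": {f: float(rng.normal(90, 30)) for f in FAMS}
        for i in range(5)
        for j in range(5)
    }
    assignments = classify_sequences(table_from(rows), flat_cutoffs())
    assert sorted(a.seq_id for a in assignments) == sorted(rows)


def test_raising_a_cutoff_is_monotone():
    rng = np.random.default_rng(8)
    rows = {
        f"SPEC{chr(65+i)}_{i}": {f: float(rng.normal(100, 25)) for f in FAMS}
        for i in range(40)
    }
    table = table_from(rows)

    def nsp1_count(nsp1_cut):
        cutoffs = [CladeCutoff("NSP1", nsp1_cut, 1, 0, False)] + [
            CladeCutoff(f, 100.0, 1, 0, False) for f in FAMS[1:]
        ]
        return sum(
            a.subfamily == "NSP1" for a in classify_sequences(table, cutoffs)
        )

    counts = [nsp1_count(c) for c in (60, 80, 100, 120, 140)]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# species complements
# ---------------------------------------------------------------------------

def assignments_for(labels: dict[str, str]):
    table = table_from(
        {
            sid: {f: (150.0 if f == fam else 0.0) for f in FAMS}
            for sid, fam in labels.items()
        }
    )
    return classify_sequences(table, flat_cutoffs())


def test_four_nsp1_paralogs_complement():
    # the moss pattern: four NSP1 paralogs and nothing else
    labels = {f"PHYPA_{i}": "NSP1" for i in range(1, 5)}
    assignments = assignments_for(labels)
    assert species_complement(assignments, "PHYPA") == {
        "NSP1": 4, "NSP2": 0, "RAM1": 0, "RAD1": 0,
    }


def test_unknown_species_is_error():
    assignments = assignments_for({"PHYPA_1": "NSP1"})
    with pytest.raises(ArgumentError):
        species_complement(assignments, "NOONE")


def test_species_with_only_unassigned_gets_zero_row():
    table = table_from({"MARPO_1": {f: -10.0 for f in FAMS}})
    assignments = classify_sequences(table, flat_cutoffs())
    assert species_complement(assignments, "MARPO") == {f: 0 for f in FAMS}


def test_dedupe_restoration_counts_removed_ids():
    labels = {"TAKLE_1": "RAM1"}
    assignments = assignments_for(labels)
    removed_map = {"TAKLE_1": ["TAKLE_2"]}
    counts = species_complement(assignments, "TAKLE", removed_map=removed_map)
    assert counts["RAM1"] == 2
    # a duplicate observed in another species is restored under that species
    removed_other = {"TAKLE_1": ["MARPO_9"]}
    counts2 = species_complement(assignments, "MARPO", removed_map=removed_other)
    assert counts2["RAM1"] == 1
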