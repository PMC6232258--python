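import math

import numpy as np
import pytest

from oracles import brute_force_forward
from conftest import make_random_hmm

from symgras.errors import BuildError, ScoringError
from symgras.profile_hmm import (
    BuildParams,
    build_profile_hmm,
    forward_score,
    read_hmm,
    viterbi_path,
    write_hmm,
)
from symgras.seqio import AMINO_ACIDS, MultipleAlignment, ProteinSequence


def seq(residues, sid="TESTS_1"):
    return ProteinSequence(sid, residues)


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def test_laplace_emission_from_identical_rows():
    msa = MultipleAlignment.from_rows(
        [("SPECA_1", "ACD"), ("SPECB_1", "ACD"), ("SPECC_1", "ACD")]
    )
    hmm = build_profile_hmm(msa, BuildParams(), "t")
    assert hmm.n_match == 3
    # Laplace: (3 observed + 1) / (3 + 20)
    assert hmm.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(4 / 23)
    assert hmm.match_emissions[0].sum() == pytest.approx(1.0, abs=1e-12)


def test_gappy_column_excluded_from_match_states():
    rows = [
        ("SPECA_1", "A-CD"),
        ("SPECB_1", "A-CD"),
        ("SPECC_1", "AKCD"),
        ("SPECD_1", "A-CD"),
        ("SPECE_1", "A-CD"),
    ]
    hmm = build_profile_hmm(MultipleAlignment.from_rows(rows), BuildParams(), "t")
    # column 2 has gap fraction 0.8 > 0.5 threshold
    assert hmm.n_match == 3
    assert hmm.match_columns == (1, 3, 4)


def test_no_match_column_is_build_error():
    rows = [("SPECA_1", "A-"), ("SPECB_1", "-C")]
    with pytest.raises(BuildError, match="threshold"):
        build_profile_hmm(
            MultipleAlignment.from_rows(rows),
            BuildParams(match_column_gap_threshold=0.2),
            "t",
        )


def test_generator_seed_alignment_yields_one_match_state_per_column():
    from symgras.synthetic_data import SimulationConfig, simulate_dataset

    config = SimulationConfig(n_species=12, domain_length=60, indel_rate=0.0, seed=5)
    ds = simulate_dataset(config)
    hmm = build_profile_hmm(ds.seed_alignments["NSP2"], BuildParams(), "NSP2")
    assert hmm.n_match == 60


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def perfect_single_state_hmm():
    import numpy as np
    from symgras.profile_hmm import ProfileHMM

    t = {k: np.zeros(0) for k in ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")}
    em = np.zeros((1, 20))
    em[0, 0] = 1.0
    return ProfileHMM(
        name="toy",
        n_match=1,
        match_emissions=em,
        insert_emissions=np.zeros((0, 20)),
        transitions=dict(BM=1.0, BD=0.0, **t),
        background=np.full(20, 1 / 20),
    )


def test_single_match_state_closed_form():
    hmm = perfect_single_state_hmm()
    rec = forward_score(hmm, seq("A"))
    assert rec.bit_score == pytest.approx(math.log2(20), abs=1e-12)
    path, bits = viterbi_path(hmm, seq("A"))
    assert path == ["begin", "M1", "end"]
    assert bits == pytest.approx(math.log2(20), abs=1e-12)


def test_empty_sequence_is_scoring_error():
    hmm = perfect_single_state_hmm()
    bad = ProteinSequence.__new__(ProteinSequence)
    object.__setattr__(bad, "id", "TESTS_e")
    object.__setattr__(bad, "residues", "")
    object.__setattr__(bad, "source_tag", None)
    with pytest.raises(ScoringError):
        forward_score(hmm, bad)


def test_forward_matches_bruteforce_on_small_models():
    rng = np.random.default_rng(7)
    for _ in range(25):
        m = int(rng.integers(1, 4))
        hmm = make_random_hmm(m, rng)
        L = int(rng.integers(1, 5))
        s = "".join(rng.choice(list("ACDE"), size=L))
        got = forward_score(hmm, seq(s)).bit_score
        want = brute_force_forward(hmm, s)
        assert got == pytest.approx(want, abs=1e-9)


def test_viterbi_never_exceeds_forward():
    rng = np.random.default_rng(13)
    for _ in range(1000):
        m = int(rng.integers(1, 6))
        hmm = make_random_hmm(m, rng)
        L = int(rng.integers(1, 9))
        s = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        f = forward_score(hmm, seq(s)).bit_score
        v = viterbi_path(hmm, seq(s))[1]
        assert v <= f + 1e-9


def test_score_invariant_under_id_relabeling():
    rng = np.random.default_rng(3)
    hmm = make_random_hmm(4, rng)
    s = "ACDEFGHIK"
    a = forward_score(hmm, seq(s, "AAAAA_1")).bit_score
    b = forward_score(hmm, seq(s, "ZZZZZ_9")).bit_score
    assert a == b


def test_consensus_scores_above_reversed_on_conserved_profiles():
    from symgras.synthetic_data import SimulationConfig, simulate_subfamily_profiles

    rng = np.random.default_rng(11)
    wins = 0
    config = SimulationConfig(seed=11, domain_length=40)
    profiles = simulate_subfamily_profiles(config)
    prof = profiles["NSP1"]
    consensus = "".join(AMINO_ACIDS[i] for i in prof.argmax(axis=1))
    rows = []
    for r in range(8):
        draw = [
            AMINO_ACIDS[np.searchsorted(prof[c].cumsum(), rng.random())]
            for c in range(40)
        ]
        rows.append((f"SPEC{chr(65 + r)}_1", "".join(draw)))
    hmm = build_profile_hmm(MultipleAlignment.from_rows(rows), BuildParams(), "NSP1")
    for _ in range(100):
        draw = "".join(
            AMINO_ACIDS[np.searchsorted(prof[c].cumsum(), rng.random())]
            for c in range(40)
        )
        fwd = forward_score(hmm, seq(draw)).bit_score
        rev = forward_score(hmm, seq(draw[::-1])).bit_score
        wins += int(fwd >= rev)
    assert wins >= 95


def test_model_from_identical_copies_beats_shuffles():
    s = "ACDEFGHIKLMNPQRSTVWY" * 2
    rows = [(f"SPEC{chr(65+i)}_1", s) for i in range(5)]
    hmm = build_profile_hmm(MultipleAlignment.from_rows(rows), BuildParams(), "t")
    own = forward_score(hmm, seq(s)).bit_score
    rng = np.random.default_rng(2)
    shuffled = []
    for _ in range(100):
        arr = np.array(list(s))
        rng.shuffle(arr)
        shuffled.append(forward_score(hmm, seq("".join(arr))).bit_score)
    assert own > np.mean(shuffled)


def test_viterbi_tie_prefers_match_over_delete():
    # two equally likely explanations for one residue under a 1-state model:
    # emit via match or skip via delete with the residue in the flank; the
    # match path must be returned.
    import numpy as np
    from symgras.profile_hmm import ProfileHMM

    t = {k: np.zeros(0) for k in ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")}
    em = np.full((1, 20), 1 / 20)  # match emits background: 0-bit emission
    hmm = ProfileHMM(
        name="tie",
        n_match=1,
        match_emissions=em,
        insert_emissions=np.zeros((0, 20)),
        transitions=dict(BM=0.5, BD=0.5, **t),
        background=np.full(20, 1 / 20),
    )
    path, bits = viterbi_path(hmm, seq("A"))
    assert path == ["begin", "M1", "end"]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_hmm_roundtrip_preserves_scores(tmp_path, toy_msa):
    hmm = build_profile_hmm(toy_msa, BuildParams(), "NSP1")
    p = tmp_path / "nsp1.hmm"
    write_hmm(hmm, p)
    back = read_hmm(p)
    assert back.name == "NSP1"
    assert back.n_match == hmm.n_match
    assert back.match_columns == hmm.match_columns
    s = seq("ACDEFGHIK")
    assert forward_score(back, s).bit_score == pytest.approx(
        forward_score(hmm, s).bit_score, abs=1e-9
    )


def test_normalization_invariants_after_build(toy_msa):
    hmm = build_profile_hmm(toy_msa, BuildParams(pseudocount_weight=0.3), "t")
    assert np.abs(hmm.match_emissions.sum(axis=1) - 1).max() < 1e-9
    if hmm.n_match > 1:
        assert np.abs(hmm.insert_emissions.sum(axis=1) - 1).max() < 1e-9
        for src in "MID":
            total = sum(hmm.transitions[src + dst] for dst in "MID")
            assert np.abs(total - 1).max() < 1e-9
    assert hmm.transitions["BM"] + hmm.transitions["BD"] == pytest.approx(1.0)
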