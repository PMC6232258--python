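import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from symgras.clade_tools import parse_tree
from symgras.evolution import CopyNumberMatrix
from symgras.profile_hmm import ProfileHMM
from symgras.seqio import MultipleAlignment

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BRYOPHYTE_NEWICK = "(hornworts,(liverworts,(Takakia,(Sphagnum,Bryophytina))));"
BRYOPHYTE_SPECIES = ["hornworts", "liverworts", "Takakia", "Sphagnum", "Bryophytina"]
SUBFAMS = ["NSP1", "NSP2", "RAM1", "RAD1"]

# Observed complements: Takakia carries the full set with expansions, the
# crown-group mosses (Bryophytina) expanded NSP1 but lost the other three,
# liverworts lack RAM1 and hornworts lack NSP2/RAD1.
BRYOPHYTE_COUNTS = {
    "Takakia": [2, 1, 2, 3],
    "Sphagnum": [1, 0, 0, 0],
    "Bryophytina": [4, 0, 0, 0],
    "liverworts": [1, 1, 0, 1],
    "hornworts": [1, 0, 1, 0],
}


@pytest.fixture()
def bryophyte_tree():
    return parse_tree(BRYOPHYTE_NEWICK)


@pytest.fixture()
def bryophyte_matrix():
    counts = np.array([BRYOPHYTE_COUNTS[sp] for sp in BRYOPHYTE_SPECIES])
    return CopyNumberMatrix(list(BRYOPHYTE_SPECIES), list(SUBFAMS), counts)


@pytest.fixture()
def toy_msa():
    return MultipleAlignment.from_rows(
        [
            ("SPECA_1", "ACDE-FGHIK"),
            ("SPECB_1", "ACDE-FGHIK"),
            ("SPECC_1", "ACDEQF-HIK"),
        ]
    )


def make_random_hmm(m: int, rng: np.random.Generator) -> ProfileHMM:
    """A random valid model, for property tests and oracle comparisons."""
    me = rng.dirichlet(np.ones(20), size=m)
    ie = rng.dirichlet(np.ones(20), size=max(m - 1, 0)) if m > 1 else np.zeros((0, 20))
    b = rng.dirichlet(np.ones(2))
    tr = {"BM": float(b[0]), "BD": float(b[1])}
    for src in "MID":
        mat = rng.dirichlet(np.ones(3), size=max(m - 1, 0))
        for d, dst in enumerate("MID"):
            tr[src + dst] = mat[:, d] if m > 1 else np.zeros(0)
    return ProfileHMM(
        name=f"rand{m}",
        n_match=m,
        match_emissions=me,
        insert_emissions=ie,
        transitions=tr,
        background=np.full(20, 0.05),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset (the study conditions)."""
    from symgras.synthetic_data import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run on the default dataset."""
    from symgras.pipeline import config_for_synthetic_dataset, run_pipeline

    base = tmp_path_factory.mktemp("default_run")
    default_dataset.write(base / "data")
    config = config_for_synthetic_dataset(
        base / "data", output_dir=str(base / "run"), seed=1
    )
    return run_pipeline(config)
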