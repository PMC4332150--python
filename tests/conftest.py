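import numpy as np
import pytest

import fractionscope as fs


@pytest.fixture
def tiny_design():
    """1 chromatin sample + 1 soluble sample + 4 controls."""
    purs = [
        fs.Purification("s_chr", "BAIT001", "chromatin", "sample"),
        fs.Purification("s_sol", "BAIT001", "soluble", "sample"),
        fs.Purification("c1", fs.CONTROL, "chromatin", "control"),
        fs.Purification("c2", fs.CONTROL, "chromatin", "control"),
        fs.Purification("c3", fs.CONTROL, "soluble", "control"),
        fs.Purification("c4", fs.CONTROL, "soluble", "control"),
    ]
    return fs.ExperimentDesign(purs)


@pytest.fixture
def tiny_matrix(tiny_design):
    preys = [fs.PreyInfo("P1", 100), fs.PreyInfo("P2", 200),
             fs.PreyInfo("P3", 300)]
    counts = np.array([
        [8, 6, 8, 8, 8, 8],
        [2, 1, 1, 1, 1, 1],
        [5, 0, 0, 0, 0, 0],
    ])
    return fs.CountMatrix.from_preys(preys, tiny_design.ids, counts)


@pytest.fixture(scope="session")
def small_sim():
    """A quick simulated dataset shared across tests (fixed seed)."""
    cfg = fs.SimulationConfig(
        n_baits=8, n_preys=400, n_unrelated_controls=10, vector_controls=3,
        replicates_per_bait_fraction=2, replicated_baits_per_fraction=0,
        edge_density=8.0, seed=20240117,
    )
    return fs.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full scoring chain on the small simulation."""
    cm, design, truth = small_sim
    masked, ledger = fs.mask_bait_self(cm, design)
    bg = fs.estimate_background(masked, design)
    scores = fs.score_interactions(masked, design, bg)
    hcips = fs.call_hcips(scores, bg, ledger)
    return {"cm": cm, "design": design, "truth": truth, "masked": masked,
            "ledger": ledger, "bg": bg, "scores": scores, "hcips": hcips}
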