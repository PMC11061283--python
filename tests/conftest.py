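import numpy as np
import pandas as pd
import pytest

import sweepscan as sw
from sweepscan.trajectory_rank import TrajectoryModel


@pytest.fixture(scope="session")
def tiny_sim_config():
    """A small neutral three-population panel configuration."""
    return sw.SimConfig(seed=11, S=400, L=200_000, n_target=12, n_ref=12, n_out=12)


@pytest.fixture(scope="session")
def tiny_panel(tiny_sim_config):
    panel, truth = sw.simulate_panel(tiny_sim_config)
    return panel, truth


@pytest.fixture(scope="session")
def study_sweep_panel():
    """One study-scale panel (54+74+54 diploids, 5,000 SNPs) with a sweep."""
    cfg = sw.SimConfig(seed=42, sweep=sw.SweepSpec())
    panel, truth = sw.simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def trajectory_model():
    """Default trajectory model with final distributions pre-computed."""
    model = TrajectoryModel()
    for s in model.s_grid:
        model.final_distribution(s)
    return model


@pytest.fixture()
def manifest_for(tiny_panel):
    panel, _ = tiny_panel
    role = {"TGT": "target", "REF": "reference", "OUT": "outgroup"}
    rows = [(s, p, role[p]) for s, p in zip(panel.sample_ids, panel.populations)]
    return sw.PopulationManifest(
        pd.DataFrame(rows, columns=["sample_id", "population", "role"]))
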