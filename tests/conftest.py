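import numpy as np
import pandas as pd
import pytest

from devconnectome.branching import BranchProfile
from devconnectome.io import Connectome, NeuronTable
from devconnectome.synthetic import SyntheticConfig, generate_worm


@pytest.fixture(scope="session")
def small_profile():
    """Branch profile yielding compact trees (~40-80 leaves) for fast tests."""
    return BranchProfile(p1_early=1.0, p2_early=0.8, p1_late=0.25,
                         p2_late=0.2, cutoff=7)


@pytest.fixture(scope="session")
def small_config(small_profile):
    return SyntheticConfig(seed=11, profile=small_profile)


@pytest.fixture(scope="session")
def small_worm(small_config):
    """One compact synthetic worm shared across tests (read-only)."""
    return generate_worm(small_config)


@pytest.fixture(scope="session")
def default_worm():
    """One full-size synthetic worm at the default study conditions."""
    return generate_worm(SyntheticConfig(seed=3))


@pytest.fixture()
def toy_table():
    """Six hand-written neurons with full attributes."""
    df = pd.DataFrame({
        "name": ["AL", "AR", "B", "C", "DL", "DR"],
        "x_ap": [0.0, 0.02, 0.3, 0.6, 1.0, 1.04],
        "y_dv": [0.03, -0.03, 0.0, 0.01, 0.02, -0.02],
        "proc_cat": ["S", "S", "M", "M", "L", "L"],
        "birth_time": [250.0, 255.0, 400.0, 900.0, 1500.0, 1510.0],
        "birth_stage": ["Embryo", "Embryo", "Embryo", "L1", "L2", "L2"],
        "lineage_name": ["ABplaa", "ABpraa", "ABalp", "ABarp",
                         "ABplpap", "ABprpap"],
        "ganglion": ["G1", "G1", "G2", "G2", "G9", "G9"],
        "func_type": ["sensory", "sensory", "inter", "inter", "motor", "motor"],
        "partner": ["AR", "AL", pd.NA, pd.NA, "DR", "DL"],
        "sym_origin": ["symmetric_blastomere", "symmetric_blastomere",
                       "unpaired", "unpaired",
                       "symmetric_blastomere", "symmetric_blastomere"],
        "circuits": ["F1|F2", "F1|F2", "F2", pd.NA, "F3", "F3"],
        "module_id": [1, 1, 1, 2, 2, 2],
    })
    return NeuronTable(df)


@pytest.fixture()
def toy_connectome(toy_table):
    """Hand-wired 6-neuron connectome over the toy table."""
    names = toy_table.names
    n = len(names)
    syn = np.zeros((n, n), dtype=np.int8)
    gap = np.zeros((n, n), dtype=np.int8)
    idx = {nm: i for i, nm in enumerate(names)}

    def add_syn(pre, post):
        syn[idx[post], idx[pre]] = 1  # A[i, j] = 1 iff j -> i

    for pre, post in [("AL", "AR"), ("AR", "AL"), ("AL", "B"), ("B", "C"),
                      ("C", "DL"), ("DL", "DR"), ("AR", "B")]:
        add_syn(pre, post)
    for a, b in [("AL", "AR"), ("DL", "DR"), ("B", "C")]:
        gap[idx[a], idx[b]] = gap[idx[b], idx[a]] = 1
    return Connectome(names, syn, gap)


def random_connectome(n, p_syn=0.3, p_gap=0.2, seed=0):
    """Small random connectome for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    syn = (rng.random((n, n)) < p_syn).astype(np.int8)
    np.fill_diagonal(syn, 0)
    g = np.triu(rng.random((n, n)) < p_gap, k=1)
    gap = (g | g.T).astype(np.int8)
    return Connectome([f"n{i}" for i in range(n)], syn, gap)
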