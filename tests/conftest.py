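import numpy as np
import pandas as pd
import pytest

from lnpstruct.synthetic_data import SyntheticBilayerSpec, make_bilayer_trajectory
from lnpstruct.trajectory_model import Topology, Trajectory


@pytest.fixture(scope="session")
def noiseless_bilayer():
    """Small frame-constant bilayer with exact cone geometry (r_h=4,
    r_t=6, truth CPP_V = 76/48)."""
    spec = SyntheticBilayerSpec(
        n_lipids_per_leaflet=4, positional_noise_sd=0.0, n_frames=5, seed=0
    )
    return make_bilayer_trajectory(spec)


@pytest.fixture(scope="session")
def noisy_bilayer():
    spec = SyntheticBilayerSpec(
        n_lipids_per_leaflet=9, positional_noise_sd=0.1, n_frames=20, seed=11
    )
    return make_bilayer_trajectory(spec)


def single_lipid_system(head_xyz, tail_xyz, masses=None, terminal=None):
    """One-lipid, one-frame system from explicit head/tail coordinates.

    ``terminal`` marks which tail atoms are chain ends (default all).
    """
    head_xyz = np.asarray(head_xyz, dtype=float)
    tail_xyz = np.asarray(tail_xyz, dtype=float)
    n_h, n_t = len(head_xyz), len(tail_xyz)
    if terminal is None:
        terminal = [True] * n_t
    if masses is None:
        masses = [1.0] * (n_h + n_t)
    rows = []
    for i in range(n_h):
        rows.append(dict(atom_id=i + 1, lipid_id=1, lipid_type="ionizable",
                         charge_state="neutral", role="head",
                         is_terminal_tail=False,
                         reference_kind="head_N" if i == 0 else "none",
                         mass=masses[i]))
    for j in range(n_t):
        rows.append(dict(atom_id=n_h + j + 1, lipid_id=1, lipid_type="ionizable",
                         charge_state="neutral", role="tail",
                         is_terminal_tail=terminal[j], reference_kind="none",
                         mass=masses[n_h + j]))
    topo = Topology(pd.DataFrame(rows))
    coords = np.concatenate([head_xyz, tail_xyz])[None, :, :]
    traj = Trajectory(times=np.array([0.0]), coords=coords,
                      box=np.array([[100.0, 100.0, 100.0]]))
    return traj, topo


@pytest.fixture
def make_single_lipid():
    return single_lipid_system
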