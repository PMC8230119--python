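import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from yarivmd import synth, trajio


@pytest.fixture()
def yariv_dimer():
    """Ideal parallel Yariv-mimic dimer (1 frame, no jitter)."""
    top, traj, truth = synth.gen_rigid_stack(n_units=2, twist_deg=0.0,
                                             rise=3.5, n_frames=1, seed=0)
    return top, traj, truth


@pytest.fixture()
def yariv_tetramer_twisted():
    """4-unit stack with +10 degree per-unit twist, no jitter."""
    top, traj, truth = synth.gen_rigid_stack(n_units=4, twist_deg=10.0,
                                             rise=3.5, n_frames=1, seed=0)
    return top, traj, truth


@pytest.fixture()
def benzene_system():
    names, elements, bonds, coords = synth.build_benzene()
    top = trajio.MolecularTopology(names, elements, np.zeros(6, int),
                                   ["BNZ"] * 6, bonds)
    return top, coords
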