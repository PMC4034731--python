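import numpy as np
import pytest

from fkbpscreen.synth import (
    PlantedQsarSpec,
    PlantedTrajSpec,
    gen_qsar_table,
    gen_ss_fixtures,
    gen_trajectory,
)
from fkbpscreen.traj.core import Trajectory


@pytest.fixture(scope="session")
def clean_qsar():
    """Noiseless planted 37-row table (30/7 split)."""
    return gen_qsar_table(PlantedQsarSpec(sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_qsar():
    """Planted table with sigma = 0.1 pIC50 units of Gaussian noise."""
    return gen_qsar_table(PlantedQsarSpec(sigma=0.1, seed=11))


@pytest.fixture(scope="session")
def toy_traj():
    """100-frame toy trajectory with planted H-bond/torsion/jitter."""
    return gen_trajectory(PlantedTrajSpec(seed=7))


@pytest.fixture(scope="session")
def ss_fixtures():
    """Ideal helix / antiparallel sheet / extended-chain fixtures."""
    return gen_ss_fixtures()


def make_trajectory(coords, masses=None, names=None, resids=None,
                    resnames=None, times=None, radii=None):
    """Minimal Trajectory wrapper around raw (n_frames, n_atoms, 3)
    coordinates for closed-form tests."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return Trajectory(
        names=np.array(names if names is not None
                       else [f"A{i}" for i in range(n)], dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resids=np.asarray(resids if resids is not None else np.ones(n, int)),
        resnames=np.array(resnames if resnames is not None
                          else ["TOY"] * n, dtype=object),
        masses=np.asarray(masses if masses is not None else np.ones(n)),
        radii=np.asarray(radii if radii is not None else np.full(n, 1.7)),
        times=np.asarray(times if times is not None
                         else np.arange(len(coords), dtype=float)),
        coords=coords,
    )
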