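import numpy as np
import pytest

import equivs
from equivs.model import EquiVS, EquiVSConfig


@pytest.fixture(scope="session")
def toluene_ensemble():
    """A small aromatic molecule with the default ten conformers."""
    return equivs.prepare_ensemble(
        "Cc1ccccc1", seed=7, molecule_id="toluene", label=5.5
    )


@pytest.fixture(scope="session")
def sulfonamide_ensemble():
    return equivs.prepare_ensemble(
        "Cc1ccc(S(N)(=O)=O)cc1", seed=3, molecule_id="tosylamide", label=7.0
    )


@pytest.fixture(scope="session")
def small_graphs(toluene_ensemble, sulfonamide_ensemble):
    """Three labeled graphs with the default ensemble size."""
    ethanol = equivs.prepare_ensemble("CCO", seed=5, molecule_id="ethanol", label=4.0)
    return [
        equivs.assemble_graph(toluene_ensemble),
        equivs.assemble_graph(sulfonamide_ensemble),
        equivs.assemble_graph(ethanol),
    ]


@pytest.fixture(scope="session")
def tiny_model():
    """Full-variant model with a small hidden width for fast property tests."""
    return EquiVS(EquiVSConfig(hidden_dim=16, seed=11))


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(0, 5.0, size=3)
    return R.as_matrix(), t
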