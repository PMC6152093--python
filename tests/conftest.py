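import numpy as np
import pytest

import trajlens as tl


@pytest.fixture
def chain10():
    return tl.build_chain(10)


@pytest.fixture
def chain30():
    return tl.build_chain(30)


@pytest.fixture
def all_sel(chain10):
    return tl.make_selection(chain10, "all")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def planted_traj(chain30):
    """Planted-mode trajectory with its ground truth (mode, amplitudes)."""
    mode = tl.make_localized_mode(chain30, 10, 16, seed=7)
    spec = tl.PlantedModeSpec(
        mode=mode, amplitude_sd=1.0, amplitude_mean=4.0, noise_sd=0.1,
        n_frames=1500, seed=7,
    )
    traj, amplitudes = tl.generate_planted_mode_trajectory(chain30, spec)
    return traj, mode, amplitudes


@pytest.fixture
def two_ion():
    spec = tl.ToyComplexSpec(geometry="two-ion", n_frames=3, seed=11)
    return tl.generate_toy_complex(spec)


@pytest.fixture
def helix_pair():
    spec = tl.ToyComplexSpec(
        geometry="helix-pair", receptor_atoms=16, ligand_atoms=8,
        n_frames=3, seed=11,
    )
    return tl.generate_toy_complex(spec)
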