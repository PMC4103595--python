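import numpy as np
import pytest

from flexbench import SyntheticSpec, make_ensemble, sigma_shape


@pytest.fixture
def helix_ensemble():
    """A 50-residue, 20-model jittered ensemble plus its RMSF oracle."""
    spec = SyntheticSpec(
        n_residues=50,
        n_models=20,
        sigma=sigma_shape(50, "terminal-ramp", base=0.3, amp=1.0),
        max_rotation_deg=30.0,
        max_translation=5.0,
        seed=42,
    )
    return make_ensemble(spec)


@pytest.fixture
def rigid_only_ensemble():
    """Identical conformers under random rigid transforms (zero true RMSF)."""
    spec = SyntheticSpec(
        n_residues=30,
        n_models=8,
        sigma=0.0,
        max_rotation_deg=60.0,
        max_translation=10.0,
        seed=7,
    )
    ensemble, _ = make_ensemble(spec)
    return ensemble


def random_points(n, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n, 3))
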