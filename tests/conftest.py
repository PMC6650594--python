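import importlib.util
import pathlib

import numpy as np
import pytest

from mrirepro import synthetic

REPO_ROOT = pathlib.Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def acceptance_mod():
    """The acceptance script, loaded as a module (single source of the
    published summary-table inputs)."""
    path = REPO_ROOT / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("acceptance_script", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A reduced phantom grid that keeps ROI geometry valid but runs fast."""
    return synthetic.AcrPhantomSpec(
        grid_shape=(128, 128, 11),
        voxel_size_mm=(0.977, 0.977, 10.0),
        cylinder_radius_mm=40.0,
        signal_level=100.0,
        noise_sigma=0.0,
        bias_amplitude=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def scheme_5_30():
    return synthetic.default_scheme(n_b0=5, n_dw=30, b=1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def constant_tensor_field(shape, eigs, spacing=(1.0, 1.0, 1.0)):
    coeffs = np.zeros(tuple(shape) + (6,))
    coeffs[...] = [eigs[0], 0.0, 0.0, eigs[1], 0.0, eigs[2]]
    return synthetic.make_tensor_field(coeffs, voxel_size_mm=spacing)
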