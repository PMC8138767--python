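import warnings
from dataclasses import replace

import pytest

from spopbind import AnisotropyEndpoints, SimulationConfig


@pytest.fixture
def endpoints():
    return AnisotropyEndpoints(r_free=0.08, r_bound=0.20, g=1.0)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(seed=7, noise_sd_anisotropy=0.0)


@pytest.fixture
def noisy_config():
    return SimulationConfig(seed=7, noise_sd_anisotropy=0.005)


@pytest.fixture
def clean_nmr_config():
    """Planted regions, no noise, no missing residues."""
    cfg = SimulationConfig(seed=11)
    return replace(cfg, nmr=replace(cfg.nmr, missing_fraction=0.0, noise_sd_intensity=0.0))


@pytest.fixture(autouse=True)
def _no_convergence_warnings_noise():
    """Replicate-exclusion warnings are expected in Monte-Carlo loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
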