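import numpy as np
import pytest

import prmquant as pq


@pytest.fixture
def noise_free_cfg():
    """Decreased-labeling scenario with sigma = 0 (deterministic areas)."""
    return pq.scenario_pack("decreased", noise_sigma=0.0, seed=11)


@pytest.fixture
def quant_table(noise_free_cfg):
    return pq.runs_to_frame(pq.simulate_experiment(noise_free_cfg))


@pytest.fixture
def roles():
    return dict(pq.PACK_NORMALIZATION_ROLES)


@pytest.fixture
def gaussian_trace():
    """Isolated Gaussian peak: amplitude 100, sigma 0.1 min, apex at 25 min."""
    rt = np.arange(24.0, 26.0, 0.01)
    amp, mu, sig = 100.0, 25.0, 0.1
    intensity = amp * np.exp(-0.5 * ((rt - mu) / sig) ** 2)
    return pq.TransitionChromatogram("PEP", "f1", rt, intensity)
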