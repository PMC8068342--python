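"""Shared fixtures: calibrated qualities and reusable cluster populations.

Calibration and the large baseline population are expensive, so they are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

import radlesion as rl


@pytest.fixture(scope="session")
def proton_quality():
    quality = rl.calibrate_baseline(seed=1)
    quality.oxygen = rl.calibrate_oxygen(quality)
    return quality


@pytest.fixture(scope="session")
def gamma_quality(proton_quality):
    return rl.gamma_reference(proton_quality)


@pytest.fixture(scope="session")
def helium_quality(gamma_quality):
    return rl.make_helium_quality(gamma_quality)


@pytest.fixture(scope="session")
def big_config():
    return rl.SimulationConfig(n_clusters_min=2_000_000, fixed_count=True,
                               seed=42)


@pytest.fixture(scope="session")
def baseline_population(proton_quality, big_config):
    rng = np.random.default_rng(42)
    return rl.generate_clusters(proton_quality, big_config, rng)


@pytest.fixture(scope="session")
def baseline_uniforms(baseline_population):
    return np.random.default_rng(43).random(baseline_population.n_lesions)


@pytest.fixture()
def small_config():
    return rl.SimulationConfig(n_clusters_min=50_000, fixed_count=True,
                               seed=5)
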