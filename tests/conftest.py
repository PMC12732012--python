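import numpy as np
import pytest

import centroquant as cq


@pytest.fixture(scope="session")
def noise_free_field():
    """Clean field for recovery tests: no noise, no clutter/debris,
    interphase pairs wide enough to resolve into two distinct regions."""
    params = cq.SimulationParams(
        seed=7, n_cells=10, field_shape=(520, 520), fraction_mitotic=0.4,
        centriole_separation_range=(12.0, 16.0), noise_model="none",
        golgi_clutter=False, gamma_debris_rate=0.0)
    stack, labels, truth = cq.generate_field(params)
    return params, stack, labels, truth


@pytest.fixture(scope="session")
def default_field():
    """A field at the simulator's default (noisy) conditions."""
    params = cq.SimulationParams(seed=3, n_cells=12, field_shape=(620, 620))
    stack, labels, truth = cq.generate_field(params)
    return params, stack, labels, truth


def expected_intensity(truth, params, channel, pixels):
    """Analytic rendering model evaluated at integer pixels (no noise):
    background + cytoplasm (target only, inside cells) + all truncated
    Gaussian spots. The independent oracle for measurement tests."""
    pixels = np.asarray(pixels)
    vals = np.full(len(pixels), params.background_level, dtype=float)
    if channel == "target":
        inside = truth.label_map[pixels[:, 0], pixels[:, 1]] > 0
        vals[inside] += params.cytoplasm_level
    amp_col = {"gamma": "gamma_amplitude", "target": "target_amplitude"}[channel]
    for spot in truth.spots.itertuples():
        d2 = ((pixels[:, 0] - spot.row) ** 2 + (pixels[:, 1] - spot.col) ** 2)
        contrib = getattr(spot, amp_col) * np.exp(
            -d2 / (2.0 * params.spot_sigma ** 2))
        contrib[d2 > (4.0 * params.spot_sigma) ** 2] = 0.0
        vals += contrib
    return vals
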