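import numpy as np
import pytest

import protondqa as pq
from protondqa.evaluation import measure


@pytest.fixture(scope="session")
def pattern():
    return pq.default_pattern()


@pytest.fixture(scope="session")
def nominal_grid(pattern):
    """Noiseless measurement of the nominal pattern at native pitch."""
    return pq.simulate_measurement(pattern, pq.TruthParams())


@pytest.fixture(scope="session")
def commissioned(pattern, nominal_grid):
    """(baseline, pattern-with-fitted-spot-baselines) from the nominal grid.

    Mirrors clinical commissioning: the baseline is what the analysis
    measures on a nominal day, so systematic sampling effects cancel in
    every subsequent deviation.
    """
    metrics, fits = measure(nominal_grid, pattern)
    return pq.baseline_from_session(metrics, fits, pattern)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


def gaussian_spot_grid(sigma, pitch=7.6, n=9, amplitude=1.0, mu=(0.0, 0.0),
                       noise_pct=0.0, seed=0, background=0.0):
    """A single sampled Gaussian spot on an odd, pixel-centered lattice."""
    c = (np.arange(n) - (n - 1) / 2) * pitch
    X, Y = np.meshgrid(c, c[::-1])
    vals = amplitude * np.exp(
        -0.5 * (((X - mu[0]) / sigma) ** 2 + ((Y - mu[1]) / sigma) ** 2)
    )
    if noise_pct:
        g = np.random.default_rng(seed)
        vals = vals * (1 + g.normal(0, noise_pct / 100, vals.shape))
    return pq.DoseGrid(values=np.clip(vals + background, 0, None), spacing_mm=pitch)
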