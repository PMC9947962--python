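import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lamedp import default_model, default_spec, simulate_pattern
from lamedp.form_factor_fit import DEFAULT_BOUNDS
from lamedp.synthetic_data import GaussianBilayerModel


@pytest.fixture(scope="session")
def truth_model():
    """Generator ground truth: typical gel-phase PC bilayer."""
    return default_model()


@pytest.fixture(scope="session")
def noise_free_profile():
    """Default single-lattice pattern (orders 1, 2, 4), no noise."""
    return simulate_pattern(default_spec(noise_sd_fraction=0.0))


@pytest.fixture(scope="session")
def random_models():
    """100 seeded random bilayer models inside the default fit bounds."""
    rng = np.random.default_rng(20230208)
    models = []
    for _ in range(100):
        p = {
            name: rng.uniform(lo + 0.02 * (hi - lo), hi - 0.02 * (hi - lo))
            for name, (lo, hi) in DEFAULT_BOUNDS.items()
        }
        d = rng.uniform(60.0, 80.0)
        models.append(
            GaussianBilayerModel(
                z_H=min(p["z_H"], d / 2 - 1.0),
                sigma_H=p["sigma_H"],
                sigma_C=p["sigma_C"],
                rho_ratio=p["rho_ratio"],
                scale=rng.uniform(0.5, 2.0),
                d=d,
            )
        )
    return models
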