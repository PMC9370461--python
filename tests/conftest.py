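import numpy as np
import pandas as pd
import pytest

from senspi.synth import SynthConfig, generate_exposures, generate_traits, assign_latent_classes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_cohort_arrays():
    """Homoscedastic null cohort (no latent classes): exposures + trait."""
    cfg = SynthConfig(
        n_subjects=5000, n_exposures=10,
        prop_sensitive=0.0, prop_resilient=0.0, seed=42,
    )
    r = np.random.default_rng(cfg.seed)
    X, _ = generate_exposures(cfg, r)
    latent = assign_latent_classes(cfg, r)
    y = generate_traits(X, latent, cfg, r)
    return X, y, cfg


@pytest.fixture()
def toy_survival():
    """Six tie-free subjects with one binary covariate, for oracle checks."""
    return pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 0, 1, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )
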