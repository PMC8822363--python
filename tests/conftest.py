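import numpy as np
import pandas as pd
import pytest

from depictrsa import ActivationSet, SyntheticConfig, generate_activations


@pytest.fixture
def small_config():
    """12 objects, 2 layers, moderate shared fraction."""
    return SyntheticConfig(
        n_objects=12,
        n_manmade=6,
        layers={"early": 64, "late": 64},
        shared_fraction=(0.4, 0.8),
        latent_dim=8,
        noise_sd=0.1,
        seed=11,
    )


@pytest.fixture
def small_multi(small_config):
    return generate_activations(small_config)


@pytest.fixture
def toy_acts():
    """Hand-sized activation set: 6 stimuli (3 objects x 2 depictions)."""
    rng = np.random.default_rng(3)
    meta = pd.DataFrame(
        {
            "object_id": ["a", "a", "b", "b", "c", "c"],
            "depiction": ["photo", "drawing"] * 3,
            "superordinate": ["manmade"] * 4 + ["natural"] * 2,
        }
    )
    return ActivationSet(rng.standard_normal((6, 10)), meta)
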