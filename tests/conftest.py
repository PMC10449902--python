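import numpy as np
import pytest

from cofrac.pipeline import train_default_classifier
from cofrac.profiles import infer_protein_profiles
from cofrac.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """One simulated experiment (default design, seed 3) with its profiles."""
    config = SimulationConfig(seed=3)
    records, standards, truth = simulate_dataset(config)
    profiles = infer_protein_profiles(records, config.n_fractions)
    return {"config": config, "records": records, "standards": standards,
            "truth": truth, "profiles": profiles}


@pytest.fixture(scope="session")
def trained_model():
    """The shared pretrained co-elution classifier (held-out training seeds)."""
    return train_default_classifier()


def gaussian_profile(apex: float, sigma: float = 2.0, n: int = 72) -> np.ndarray:
    f = np.arange(1, n + 1, dtype=float)
    return np.exp(-0.5 * ((f - apex) / sigma) ** 2)
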