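import numpy as np
import pytest

from pgmelm import GANConfig, SynthSpec, kernel_mmd, train_dynamic_gan

# the canonical strongly-separated fixture used for end-to-end sanity bounds
SEPARABLE_SPEC = SynthSpec(class_separation=6.0, seed=7)


@pytest.fixture(scope="session")
def gaussian2d():
    """200 draws from a correlated 2-D Gaussian, split fit/held-out."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.5], [0.0, 1.2]]) + [3.0, -1.0]
    return X[:100], X[100:]


@pytest.fixture(scope="session")
def trained_gans(gaussian2d):
    """GANs trained on the 2-D Gaussian fixture for three seeds.

    Session-scoped: adversarial training is the slow part of the suite and
    several behavioural tests share these models.
    """
    X_fit, _ = gaussian2d
    return {seed: train_dynamic_gan(X_fit, GANConfig(seed=seed))
            for seed in (0, 1, 2)}
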