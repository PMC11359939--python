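import numpy as np
import pytest

from ivamotor.preprocessing import apply_whitening, fit_whitening
from ivamotor.synthetic_data import generate_jbss, generate_two_class_dataset


@pytest.fixture(scope="session")
def small_jbss():
    """A small identifiable JBSS instance: K=3, M=4, distinct SCV correlations."""
    rho = np.array([0.9, 0.7, 0.5, 0.3])
    X, truth = generate_jbss(K=3, M=4, N=5000, rho=rho, seed=42)
    return X, truth


@pytest.fixture(scope="session")
def small_jbss_whitened(small_jbss):
    X, truth = small_jbss
    V = [fit_whitening(Xk) for Xk in X]
    Z = np.stack([apply_whitening(Vk, Xk) for Vk, Xk in zip(V, X)])
    return Z, V, truth


@pytest.fixture(scope="session")
def tiny_two_class():
    """A small separable two-class dataset: K=3 subjects, M=4 channels."""
    return generate_two_class_dataset(K=3, M=4, n_trials_per_class=20, T=200, seed=11)
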