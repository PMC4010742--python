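import numpy as np
import pytest

from microtrace import phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless 30-nucleus phantom (no arbors) with ground truth."""
    spec = phantom.PhantomSpec(
        seed=5, shape=(32, 96, 96),
        cell_counts={"microglia": 0, "astrocyte": 15, "neuron": 15},
        photon_scale=0, read_noise_sd=0, bias_amplitude=0,
    )
    channels, truth = phantom.generate_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def arbor_phantom():
    """Noiseless single-microglia phantom with one rendered arbor."""
    spec = phantom.PhantomSpec(
        seed=21, shape=(28, 72, 72),
        cell_counts={"microglia": 1, "astrocyte": 0, "neuron": 0},
        photon_scale=0, read_noise_sd=0, bias_amplitude=0,
    )
    channels, truth = phantom.generate_phantom(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def noisy_microglia_phantom():
    """Three-microglia phantom with photon + read noise (for seed learning)."""
    def make(seed):
        spec = phantom.PhantomSpec(
            seed=seed, shape=(24, 80, 80),
            cell_counts={"microglia": 3, "astrocyte": 0, "neuron": 0},
            photon_scale=0.05, read_noise_sd=40,
        )
        channels, truth = phantom.generate_phantom(spec)
        return spec, channels, truth
    return make


def planted_sparse_model(seed, n=147, n_atoms=8, N=400, per_signal=2):
    """Signals drawn exactly from a random planted dictionary, plus labels."""
    rng = np.random.default_rng(seed)
    D = rng.standard_normal((n, n_atoms))
    D /= np.linalg.norm(D, axis=0)
    G = np.zeros((n_atoms, N))
    for i in range(N):
        sel = rng.choice(n_atoms, per_signal, replace=False)
        G[sel, i] = (1 + rng.random(per_signal)) * np.sign(rng.standard_normal(per_signal))
    H = np.zeros((2, N))
    H[rng.integers(0, 2, N), np.arange(N)] = 1
    return D @ G, H, D, G
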