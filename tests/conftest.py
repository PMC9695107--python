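import numpy as np
import pytest

from odcseg.networks import NetworkConfig
from odcseg.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_net_config():
    """Tiny network sized for CPU test runs."""
    return NetworkConfig(image_size=64, base_channels=4)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Eight 64x64 phantoms per domain with manifest, shared across tests."""
    root = tmp_path_factory.mktemp("phantoms")
    manifest = generate_dataset(8, root, seed=77, image_size=64)
    return root, manifest


def circle_points(center=(0.0, 0.0), radius=1.0, n=360):
    """Analytic (non-rasterized) contour samples of a circle."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + radius * np.sin(th),
                     center[1] + radius * np.cos(th)], axis=1)


def ellipse_points(a, b, center=(0.0, 0.0), n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + a * np.sin(th),
                     center[1] + b * np.cos(th)], axis=1)
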