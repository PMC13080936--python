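import numpy as np
import pytest

from livespot.core_io import MovieStack
from livespot.simulator import benchmark_params, simulate_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_movie(rng):
    """Random 16-bit movie, (4, 2, 32, 32)."""
    data = rng.integers(0, 65535, size=(4, 2, 32, 32), dtype=np.uint16)
    return MovieStack(data=data, pixel_size_um=0.13, frame_interval_s=2.0,
                      channel_names=["a", "b"])


@pytest.fixture(scope="session")
def mini_benchmark():
    """Scaled-down benchmark movie: same optics/kinetics/noise, smaller field.

    (64 frames, 2 channels, 160x160, 12 spots) keeps unit tests fast while
    preserving per-spot statistics.
    """
    params = benchmark_params(seed=11, n_frames=64, fov_yx=(160, 160), n_spots=12)
    movie, truth = simulate_movie(params)
    return params, movie, truth


def gaussian_patch(shape, y0, x0, amplitude, sigma, offset=0.0):
    """Analytic noiseless Gaussian spot (shared oracle helper)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2)) + offset
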