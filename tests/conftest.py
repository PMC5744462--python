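import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_fiber(rng, n_points=51, scale=40.0):
    """Smooth random polyline resembling a tractography centroid."""
    steps = gaussian_filter1d(
        rng.normal(size=(n_points, 3)), sigma=max(4.0, n_points / 12), axis=0
    )
    pts = np.cumsum(steps, axis=0) * (scale / n_points) * 4.0
    return pts + rng.uniform(-50, 50, size=3)


def straight_fiber(start, end, n_points=51):
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    return np.asarray(start) + t * (np.asarray(end) - np.asarray(start))
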