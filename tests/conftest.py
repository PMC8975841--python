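import numpy as np
import pytest

from mucogel.diffusion_profiles import ProfileMatrix
from mucogel.synthetic_data import analytic_erfc_solution

# default analysis geometry: 2 mm profile window at 10 um/px, 30 frames at 4 min
DEFAULT_X = (np.arange(200) + 0.5) * 1e-3  # cm
DEFAULT_T = 240.0 * np.arange(1, 31)  # s


@pytest.fixture
def analytic_matrix():
    """Factory for noiseless analytic profile matrices on the default grid."""

    def make(d: float, amplitude: float = 1.0, offset: float = 0.0,
             x: np.ndarray = DEFAULT_X, t: np.ndarray = DEFAULT_T) -> ProfileMatrix:
        f = amplitude * analytic_erfc_solution(x[:, None], t[None, :], d, 1.0) + offset
        return ProfileMatrix(f=f, x_grid=x, t_grid=t)

    return make


@pytest.fixture
def spot_field():
    """Factory for images of non-overlapping Gaussian spots with known centers."""

    def make(n_spots: int, shape=(512, 512), sigma: float = 3.0, min_sep: float = 25.0,
             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        centers: list[np.ndarray] = []
        while len(centers) < n_spots:
            p = rng.uniform(20, shape[0] - 20, 2)
            if all(np.hypot(*(p - q)) > min_sep for q in centers):
                centers.append(p)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        for r, c in centers:
            img += np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
        return img, np.array(centers)

    return make
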