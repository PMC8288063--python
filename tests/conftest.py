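import numpy as np
import pytest

from visfill import network as nw
from visfill import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_arch():
    """64px U-Net with a 1x1 bottleneck (6 stride-2 layers, tiny channels)."""
    return nw.default_architecture(64, encoder_channels=(4, 8, 8, 8, 8, 16))


@pytest.fixture(scope="session")
def small_net(small_arch):
    return nw.EncoderDecoder(small_arch, seed=7)


@pytest.fixture(scope="session")
def scene_set_small():
    return sd.generate_scene_set(12, 3, 64, seed=3)


def make_grid_prf(n_per_group=16, sigma=0.5):
    """Regular-grid pRF map, ``n_per_group`` voxels per (ROI, quadrant)."""
    xs, ys, rois, quads = [], [], [], []
    g = int(np.sqrt(n_per_group))
    for roi in ("V1", "V2"):
        for quad in ("nonoccluded", "occluded"):
            x0, x1, y0, y1 = sd.quadrant_region_deg(quad)
            cx = np.linspace(x0 + 2, x1 - 2, g)
            cy = np.linspace(y0 + 2, y1 - 2, g)
            gx, gy = np.meshgrid(cx, cy)
            xs.append(gx.ravel())
            ys.append(gy.ravel())
            rois.append([roi] * n_per_group)
            quads.append([quad] * n_per_group)
    x = np.concatenate(xs)
    return sd.PRFMap(x, np.concatenate(ys), np.full(len(x), sigma),
                     np.concatenate(rois), np.concatenate(quads),
                     {"V1": (0.2, 0.1), "V2": (0.2, 0.12)}, 256)


@pytest.fixture
def grid_prf():
    return make_grid_prf


@pytest.fixture(scope="session")
def default_arch():
    """The full-size architecture config (shape algebra only; no weights)."""
    return nw.default_architecture(256)
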