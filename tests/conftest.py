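import numpy as np
import pytest

from regqa import FrameGeometry, Volume


@pytest.fixture
def small_frame() -> FrameGeometry:
    """A small anisotropic frame (thick slices, like clinical CT)."""
    return FrameGeometry((40, 40, 12), (2.0, 2.0, 5.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20100609)


def make_smooth_volume(frame: FrameGeometry, seed: int = 0, modality: str = "CT") -> Volume:
    """Smooth band-limited random image: Gaussian-filtered noise plus a
    broad quadratic ramp so it has structure at several scales."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    noise = gaussian_filter(r.normal(size=frame.shape), sigma=(3, 3, 1.5)) * 50.0
    ax = [np.linspace(-1, 1, n) for n in frame.shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    ramp = 100.0 * (1 - X**2) * (1 - Y**2) * (1 - 0.5 * Z**2)
    return Volume(noise + ramp, frame.spacing, frame.origin, modality=modality)


@pytest.fixture
def smooth_volume(small_frame) -> Volume:
    return make_smooth_volume(small_frame, seed=7)
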