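import numpy as np
import pytest

from plantarseg.synthdata import SynthSpec, generate


@pytest.fixture(scope="session")
def small_foot():
    """A normal left footprint on a 360x360 grid (half-size sensor area),
    with its programmatic ground truth."""
    return generate(
        SynthSpec(
            foot_type="normal",
            side="left",
            image_size=(360, 360),
            foot_length=210,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_foot_pair():
    """One small footprint per side, same morphology."""
    return {
        side: generate(
            SynthSpec(
                foot_type="normal",
                side=side,
                image_size=(360, 360),
                foot_length=210,
                seed=11,
            )
        )
        for side in ("left", "right")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_blob_mask(rng, shape=(64, 64), n_blobs=3, r_range=(4, 10)):
    """Random blob mask used by contour/segmentation property tests."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        r = rng.uniform(*r_range)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return np.where(mask, np.uint8(255), np.uint8(0))


def make_smooth_image(rng, shape=(64, 64), amplitude=255.0):
    """Smooth random intensity field (for gradient/edge property tests)."""
    from scipy import ndimage

    noise = rng.normal(0, 1, shape)
    smooth = ndimage.gaussian_filter(noise, sigma=6)
    smooth -= smooth.min()
    smooth *= amplitude / max(smooth.max(), 1e-9)
    return smooth.astype(np.uint8)
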