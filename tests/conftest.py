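import numpy as np
import pytest

from deltarad import (
    DiscretizedROI,
    ImageVolume,
    TumorMask,
    discretize_fixed_bin_width,
    normalize_intensity,
)


def random_roi(seed: int, max_dim: int = 8, n_levels_hint: int = 4):
    """A small random volume + mask + discretized ROI for oracle checks.

    Masks are random (possibly disconnected) with at least two voxels; the
    intensity range is chosen so the discretized ROI has a handful of gray
    levels.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(rng.integers(2, max_dim + 1)) for _ in range(3))
    vol = ImageVolume(rng.uniform(50.0, 150.0, shape))
    mask = rng.random(shape) < rng.uniform(0.4, 0.95)
    if mask.sum() < 2:
        mask.flat[:2] = True
    mask = TumorMask(mask)
    norm = normalize_intensity(vol)
    roi_range = float(np.ptp(norm.intensities[mask.voxels]))
    width = max(roi_range / n_levels_hint, 1e-6)
    roi = discretize_fixed_bin_width(norm, mask, width)
    return norm, mask, roi


def roi_from_levels(levels) -> DiscretizedROI:
    levels = np.asarray(levels, dtype=np.int64)
    return DiscretizedROI(
        levels=levels,
        n_levels=int(levels.max()),
        n_voxels=int((levels > 0).sum()),
        bin_width=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
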