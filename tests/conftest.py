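import numpy as np
import pytest

from radcorr.volume import ImageVolume, QuantizedRoi, RoiMask


def make_qroi(levels, mask=None, ng=None) -> QuantizedRoi:
    """Build a QuantizedRoi directly from an integer level grid (tests only)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim < 3:
        levels = levels.reshape(levels.shape + (1,) * (3 - levels.ndim))
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim < 3:
            mask = mask.reshape(mask.shape + (1,) * (3 - mask.ndim))
    levels = np.where(mask, levels, 0)
    if ng is None:
        ng = int(levels.max())
    return QuantizedRoi(
        levels=levels,
        mask=RoiMask(mask),
        n_levels=ng,
        codebook=np.arange(1, ng + 1, dtype=float),
        value_range=(1.0, float(ng)),
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="") -> ImageVolume:
    values = np.asarray(values, dtype=float)
    if values.ndim < 3:
        values = values.reshape(values.shape + (1,) * (3 - values.ndim))
    return ImageVolume(values, spacing, modality)


def random_roi(rng, max_dim=6, min_levels=2, max_levels=5):
    """Random small quantized ROI guaranteed to contain a neighboring pair."""
    while True:
        shape = tuple(rng.integers(2, max_dim + 1, size=3))
        ng = int(rng.integers(min_levels, max_levels + 1))
        mask = rng.random(shape) < 0.7
        if mask.sum() < 4:
            continue
        # require at least one in-mask neighbor pair so the GLCM is defined
        padded = np.pad(mask, 1)
        has_pair = False
        for ax in range(3):
            rolled = np.roll(padded, 1, axis=ax)
            if (padded & rolled).any():
                has_pair = True
                break
        if not has_pair:
            continue
        levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
        # ensure the top level is occupied so ng is the true level count
        levels.flat[np.flatnonzero(mask.ravel())[0]] = ng
        return make_qroi(levels, mask, ng)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
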