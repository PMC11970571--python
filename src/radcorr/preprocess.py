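"""Resampling, 3-sigma intensity re-segmentation, and Lloyd-Max quantization.

The preprocessing chain mirrors standard radiomics practice: volumes are
resampled to an isotropic grid with cubic interpolation, the ROI intensity
distribution is re-segmented to mean +/- 3 sigma (the Collewet rule, IBSI
re-segmentation code RS:3sigma), and the surviving intensities are discretized
to ``n_levels`` gray levels with the MSE-minimizing Lloyd-Max scalar quantizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .volume import ImageVolume, QuantizedRoi, RoiMask

__all__ = [
    "resample_isotropic",
    "collewet_resegment",
    "lloyd_quantize",
    "CollewetResult",
]

#: Convergence tolerance of the Lloyd-Max fixed point, as a fraction of the
#: quantization range width.
LLOYD_TOL_FRACTION = 1e-8
LLOYD_MAX_ITER = 500


def _resample_grid(arr: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    """Separable spline interpolation onto a ``target``-mm isotropic grid.

    Uses not-a-knot B-splines axis by axis (exact on polynomial data up to the
    spline order, unlike mirrored-boundary prefiltering).  Output grid point j
    sits at physical coordinate j*target, sharing the origin with the input.
    """
    out = np.asarray(arr, dtype=np.float64)
    for ax in range(3):
        n_old = out.shape[ax]
        old = np.arange(n_old) * spacing[ax]
        n_new = int(np.floor(old[-1] / target + 1e-9)) + 1
        new = np.arange(n_new) * target
        k = min(order, n_old - 1)
        if k == 0:
            out = np.repeat(out, n_new, axis=ax) if n_new != n_old else out
            continue
        spline = make_interp_spline(old, out, k=k, axis=ax)
        out = spline(new)
    return out


def resample_isotropic(
    vol: ImageVolume,
    mask: RoiMask,
    target_mm: float = 1.0,
    case_id: str = "",
) -> tuple[ImageVolume, RoiMask]:
    """Resample a volume and its ROI mask to an isotropic grid.

    The image is interpolated with cubic (3rd-order) splines; the mask is
    interpolated linearly and thresholded at 0.5.

    Raises
    ------
    ValueError
        If ``target_mm <= 0`` or the resampled mask comes out empty.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if all(abs(s - target_mm) < 1e-12 for s in vol.spacing_mm):
        # Grid already isotropic at the target: interpolation is the identity.
        return (
            ImageVolume(vol.values.copy(), (target_mm,) * 3, vol.modality),
            RoiMask(mask.inside.copy()),
        )
    new_values = _resample_grid(vol.values, vol.spacing_mm, target_mm, order=3)
    mask_f = _resample_grid(mask.inside.astype(np.float64), vol.spacing_mm, target_mm, order=1)
    new_inside = mask_f >= 0.5
    if not new_inside.any():
        label = case_id or vol.modality or "volume"
        raise ValueError(f"resampled ROI mask is empty for {label}")
    new_vol = ImageVolume(new_values, (target_mm,) * 3, vol.modality)
    return new_vol, RoiMask(new_inside)


@dataclass
class CollewetResult:
    mask: RoiMask
    value_range: tuple[float, float]
    mean: float
    std: float
    n_removed: int
    degenerate: bool = False


def collewet_resegment(vol: ImageVolume, mask: RoiMask) -> CollewetResult:
    """Remove ROI voxels outside mean +/- 3 sigma of the in-mask intensities.

    Statistics use the population standard deviation.  When sigma is zero the
    mask is returned unchanged with a degenerate (mu, mu) range and the result
    is flagged.
    """
    values = vol.values[mask.inside]
    mu = float(values.mean())
    sigma = float(values.std())
    if sigma == 0.0:
        return CollewetResult(mask, (mu, mu), mu, sigma, 0, degenerate=True)
    low, high = mu - 3.0 * sigma, mu + 3.0 * sigma
    keep = mask.inside & (vol.values >= low) & (vol.values <= high)
    n_removed = mask.n_voxels - int(keep.sum())
    return CollewetResult(RoiMask(keep), (low, high), mu, sigma, n_removed)


def lloyd_quantize(
    vol: ImageVolume,
    mask: RoiMask,
    value_range: tuple[float, float] | None = None,
    n_levels: int = 64,
) -> QuantizedRoi:
    """Discretize in-mask intensities to ``n_levels`` levels with Lloyd-Max.

    The codebook is initialized at the centers of ``n_levels`` equal-width bins
    over ``value_range`` and iterated to the nearest-code / centroid fixed
    point.  Empty bins keep their previous codebook value.  A value exactly
    equidistant between two codes takes the lower level, so results are
    bit-stable.  If the ROI holds fewer distinct values than ``n_levels``, the
    distinct values are mapped to consecutive levels 1..k and the effective
    level count is recorded.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = vol.values[mask.inside]
    if value_range is None:
        value_range = (float(values.min()), float(values.max()))
    low, high = float(value_range[0]), float(value_range[1])
    if low > high:
        raise ValueError("invalid value range")
    values = np.clip(values, low, high)
    distinct = np.unique(values)

    levels_grid = np.zeros(vol.shape, dtype=np.int32)

    if distinct.size < n_levels:
        # Fewer distinct intensities than requested levels: each distinct
        # value becomes its own level, in increasing order.
        lv = np.searchsorted(distinct, values) + 1
        levels_grid[mask.inside] = lv
        return QuantizedRoi(
            levels_grid,
            mask,
            n_levels,
            distinct,
            (low, high),
            n_levels_effective=int(distinct.size),
            n_iterations=0,
            mse_history=[0.0 if distinct.size == values.size else float(np.mean((values - distinct[lv - 1]) ** 2))],
        )

    width = high - low
    codebook = low + (np.arange(n_levels) + 0.5) * width / n_levels
    tol = LLOYD_TOL_FRACTION * width
    mse_history: list[float] = []
    assign = np.zeros(values.size, dtype=np.intp)
    for it in range(1, LLOYD_MAX_ITER + 1):
        boundaries = 0.5 * (codebook[:-1] + codebook[1:])
        # side='left': a value equal to a boundary goes to the lower bin.
        assign = np.searchsorted(boundaries, values, side="left")
        mse_history.append(float(np.mean((values - codebook[assign]) ** 2)))
        sums = np.bincount(assign, weights=values, minlength=n_levels)
        counts = np.bincount(assign, minlength=n_levels)
        new_codebook = codebook.copy()
        occupied = counts > 0
        new_codebook[occupied] = sums[occupied] / counts[occupied]
        movement = float(np.max(np.abs(new_codebook - codebook)))
        codebook = new_codebook
        if movement < tol:
            break
    boundaries = 0.5 * (codebook[:-1] + codebook[1:])
    assign = np.searchsorted(boundaries, values, side="left")
    mse_history.append(float(np.mean((values - codebook[assign]) ** 2)))

    if not np.all(np.diff(codebook) > 0):
        warnings.warn("Lloyd-Max codebook is not strictly increasing", stacklevel=2)
    levels_grid[mask.inside] = assign.astype(np.int32) + 1
    return QuantizedRoi(
        levels_grid,
        mask,
        n_levels,
        codebook,
        (low, high),
        n_levels_effective=int(np.unique(assign).size),
        n_iterations=it,
        mse_history=mse_history,
    )
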