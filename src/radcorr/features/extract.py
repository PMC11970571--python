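"""Full feature-vector extraction and volume normalization."""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, QuantizedRoi
from . import registry
from .matrices import NgtdmParts, build_glcm, build_glrlm, build_glszm, build_ngtdm
from .values import (
    NGTDM_EPS,
    features_glcm,
    features_glrlm,
    features_glszm,
    features_intensity,
    features_ngtdm,
)

__all__ = ["extract_all", "apply_volume_normalization"]


def _crop_to_bbox(q: QuantizedRoi) -> QuantizedRoi:
    """Restrict the grids to the ROI bounding box (pure speed optimization;
    every texture matrix depends only on in-mask voxels)."""
    idx = np.nonzero(q.mask.inside)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    if all(s == slice(0, n) for s, n in zip(sl, q.mask.shape)):
        return q
    cropped = QuantizedRoi.__new__(QuantizedRoi)
    cropped.levels = q.levels[sl]
    cropped.mask = type(q.mask).__new__(type(q.mask))
    cropped.mask.inside = q.mask.inside[sl]
    cropped.n_levels = q.n_levels
    cropped.codebook = q.codebook
    cropped.value_range = q.value_range
    cropped.n_levels_effective = q.n_levels_effective
    cropped.n_iterations = q.n_iterations
    cropped.mse_history = q.mse_history
    return cropped


def apply_volume_normalization(
    features: dict[str, float],
    ngtdm_parts: NgtdmParts | None,
    volume: float,
    eps: float = NGTDM_EPS,
) -> dict[str, float]:
    """Replace the seven volume-dependent features with their normalized form.

    ``volume`` is the ROI size (number of voxels; equal to mm^3 on the 1 mm
    isotropic analysis grid).  Type 1 divides by volume, type 2 multiplies by
    volume, and types 3/4 recompute busyness/coarseness from the NGTDM parts
    with the mean (rather than summed) absolute neighborhood difference
    s(i)/N(i) per level.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    out = dict(features)
    for fdef in registry.vn_features():
        raw = out.get(fdef.name, np.nan)
        if fdef.vn_type == 1:
            out[fdef.name] = raw / volume
        elif fdef.vn_type == 2:
            out[fdef.name] = raw * volume
        elif fdef.vn_type in (3, 4):
            if ngtdm_parts is None:
                out[fdef.name] = np.nan
                continue
            occ = ngtdm_parts.occupied
            p = ngtdm_parts.p_i[occ]
            s_mean = ngtdm_parts.s_i[occ] / ngtdm_parts.n_i[occ]
            i = (occ + 1).astype(np.float64)
            num = float((p * s_mean).sum())
            if fdef.vn_type == 4:
                out[fdef.name] = 1.0 / (eps + num)
            else:
                ipi = i * p
                den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
                out[fdef.name] = num / den if den > 0 else np.nan
    return out


def extract_all(
    q: QuantizedRoi,
    vol: ImageVolume,
    volume_normalize: bool = True,
) -> dict[str, float]:
    """Compute all 42 features plus ROI volume from a quantized ROI.

    ``vol`` supplies the raw (unquantized) intensities for the first-order
    statistics; its grid must match the quantized ROI's mask.  Families whose
    matrices are undefined on degenerate ROIs (a single voxel has no
    co-occurring pairs) propagate NaN for their features rather than failing
    the whole vector.  Returns a dict with 43 entries: the registry's 42
    feature names plus ``Volume_mm3``.
    """
    if vol.shape != q.mask.shape:
        raise ValueError("volume and quantized ROI shapes differ")
    raw_full = vol.values[q.mask.inside]
    q = _crop_to_bbox(q)  # texture matrices only see in-mask voxels
    n_vox = q.mask.n_voxels
    out: dict[str, float] = {}

    try:
        out.update(features_glcm(build_glcm(q)))
    except ValueError:
        out.update({f.name: np.nan for f in registry.FEATURES if f.family == "GLCM"})

    out.update(features_glrlm(build_glrlm(q), n_vox))
    out.update(features_glszm(build_glszm(q), n_vox))

    ngtdm_parts = build_ngtdm(q)
    if ngtdm_parts.n_valid > 0:
        out.update(features_ngtdm(ngtdm_parts))
    else:
        ngtdm_parts = None
        out.update({f.name: np.nan for f in registry.FEATURES if f.family == "NGTDM"})

    raw = raw_full
    if raw.size >= 2:
        out.update(features_intensity(raw))
    else:
        out.update({f.name: np.nan for f in registry.FEATURES if f.family == "IS"})

    if volume_normalize:
        out = apply_volume_normalization(out, ngtdm_parts, float(n_vox))

    out[registry.VOLUME_FEATURE] = n_vox * vol.voxel_volume_mm3
    # Stable ordering: registry order, then volume.
    ordered = {name: out[name] for name in registry.feature_names()}
    ordered[registry.VOLUME_FEATURE] = out[registry.VOLUME_FEATURE]
    return ordered
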