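"""Texture matrix construction from a quantized ROI.

All matrices are built in 3D at distance 1 with the merged 13-unique-direction
aggregation: the 13 offsets covering every axis, face-diagonal and
space-diagonal neighbor pair once.  Counts from all directions are accumulated
into a single matrix before any feature is computed (no per-direction
averaging).  Zones use 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..volume import QuantizedRoi

__all__ = [
    "DIRECTIONS_13",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
    "NgtdmParts",
]

#: The 13 unique 3D offsets at Chebyshev distance 1 (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def _shift_slices(d: tuple[int, int, int], shape) -> tuple[tuple, tuple]:
    """Index slices selecting (voxel, voxel+d) pairs fully inside the grid."""
    src, dst = [], []
    for step, n in zip(d, shape):
        if step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        elif step == -1:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
        else:
            src.append(slice(0, n))
            dst.append(slice(0, n))
    return tuple(src), tuple(dst)


def build_glcm(q: QuantizedRoi) -> np.ndarray:
    """Symmetric gray-level co-occurrence probabilities, shape (Ng, Ng).

    Pairs are counted for all 13 directions, both orderings, only when both
    voxels are in the mask; counts are merged and normalized to sum to 1.

    Raises
    ------
    ValueError
        If the ROI contains no in-mask neighbor pair (e.g. a single voxel),
        which leaves every GLCM feature undefined.
    """
    ng = q.n_levels
    levels = q.levels
    inside = q.mask.inside
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in DIRECTIONS_13:
        src, dst = _shift_slices(d, levels.shape)
        valid = inside[src] & inside[dst]
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T  # both orderings -> symmetric
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask voxel pairs: GLCM features undefined")
    return counts / total


def build_glrlm(q: QuantizedRoi) -> np.ndarray:
    """Run-length counts merged over the 13 directions, shape (Ng, Rmax).

    Every in-mask voxel belongs to exactly one maximal run per direction, so
    sum_{g,r} r * M[g, r] == n_voxels * 13.
    """
    levels = np.where(q.mask.inside, q.levels, 0)
    per_dir = []
    rmax = 1
    for d in DIRECTIONS_13:
        g, r = _runs_along(levels, d)
        per_dir.append((g, r))
        if r.size:
            rmax = max(rmax, int(r.max()))
    m = np.zeros((q.n_levels, rmax), dtype=np.float64)
    for g, r in per_dir:
        np.add.at(m, (g - 1, r - 1), 1.0)
    return m


def _runs_along(levels: np.ndarray, d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(level, length) of every maximal nonzero run along direction ``d``."""
    shape = np.array(levels.shape)
    dv = np.array(d)
    idx = np.indices(levels.shape).reshape(3, -1)
    prev = idx - dv[:, None]
    is_start = ((prev < 0) | (prev >= shape[:, None])).any(axis=0)
    starts = idx[:, is_start]  # (3, K) line origins
    # Longest possible line length along d within the grid.
    lmax = 0
    for step, n in zip(d, levels.shape):
        if step != 0:
            lmax = max(lmax, n)
    steps = np.arange(lmax)
    coords = starts[:, :, None] + dv[:, None, None] * steps[None, None, :]
    in_grid = ((coords >= 0) & (coords < shape[:, None, None])).all(axis=0)
    lines = np.zeros((starts.shape[1], lmax), dtype=levels.dtype)
    cc = coords[:, in_grid]
    lines[in_grid] = levels[cc[0], cc[1], cc[2]]
    # Row-wise run-length encoding: separate rows with a zero column.
    padded = np.zeros((lines.shape[0], lmax + 1), dtype=lines.dtype)
    padded[:, :lmax] = lines
    flat = padded.ravel()
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    run_levels = flat[bounds[:-1]]
    run_lengths = np.diff(bounds)
    keep = run_levels > 0
    return run_levels[keep].astype(np.intp), run_lengths[keep].astype(np.intp)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def build_glszm(q: QuantizedRoi) -> np.ndarray:
    """Zone-size counts, shape (Ng, Zmax); zones are 26-connected components
    of equal level, so sum_{g,z} z * M[g, z] == n_voxels."""
    levels = np.where(q.mask.inside, q.levels, 0)
    occupied = np.unique(levels[q.mask.inside])
    records: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for g in occupied:
        lab, n_zones = ndimage.label(levels == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        records.append((int(g), sizes))
        zmax = max(zmax, int(sizes.max()))
    m = np.zeros((q.n_levels, zmax), dtype=np.float64)
    for g, sizes in records:
        np.add.at(m, (g - 1, sizes - 1), 1.0)
    return m


@dataclass
class NgtdmParts:
    """Per-level ingredients of the neighborhood gray-tone difference features.

    Arrays are indexed by level-1 (length Ng).  ``n_i`` counts the voxels of
    each level that have at least one in-mask 26-neighbor; ``s_i`` sums, over
    those voxels, the absolute difference between the voxel's level and the
    mean level of its in-mask neighborhood; ``p_i = n_i / n_valid``.
    """

    p_i: np.ndarray
    s_i: np.ndarray
    n_i: np.ndarray
    n_valid: int

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.p_i > 0)


_KERNEL_26 = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL_26[1, 1, 1] = 0.0


def build_ngtdm(q: QuantizedRoi) -> NgtdmParts:
    inside = q.mask.inside
    levels = np.where(inside, q.levels, 0).astype(np.float64)
    nb_sum = ndimage.correlate(levels, _KERNEL_26, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(inside.astype(np.float64), _KERNEL_26, mode="constant", cval=0.0)
    valid = inside & (nb_cnt > 0.5)
    g = q.levels[valid]
    diff = np.abs(g - nb_sum[valid] / nb_cnt[valid])
    ng = q.n_levels
    n_i = np.bincount(g, minlength=ng + 1)[1:].astype(np.float64)
    s_i = np.bincount(g, weights=diff, minlength=ng + 1)[1:]
    n_valid = int(valid.sum())
    p_i = n_i / n_valid if n_valid else n_i
    return NgtdmParts(p_i=p_i, s_i=s_i, n_i=n_i, n_valid=n_valid)
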