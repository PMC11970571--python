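"""Gold-fiducial streak-artifact masking.

Metal fiducial seeds produce bright/dark streaks that radiate in-plane from
the seed on X-ray-based images (CT, cone-beam CT).  The removal algorithm
works per axial slice in 2D:

1. an artifact threshold [mu - 3 sigma, mu + 3 sigma] is estimated from ROI
   voxels on slices that contain no artifact;
2. on each artifact slice, the removal mask is the union of (a) a 5 mm disk
   around the fiducial center, (b) every in-ROI pixel outside the threshold,
   and (c) the discrete (Bresenham) line from each such pixel back to the
   fiducial center;
3. the mask is subtracted from the ROI and the volume reduction reported.

Voxels are removed, not repaired: the ROI simply shrinks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as bresenham_line

from .volume import ImageVolume, RoiMask

__all__ = [
    "FiducialAnnotation",
    "ArtifactMask",
    "artifact_threshold",
    "build_artifact_mask",
    "apply_artifact_mask",
    "save_fiducials",
    "load_fiducials",
]


@dataclass
class FiducialAnnotation:
    """Fiducial centers (voxel coordinates, z = axial slice index) and, per
    fiducial, the set of axial slices containing its artifact."""

    centers: list[tuple[int, int, int]]
    artifact_slices: list[set[int]]

    def __post_init__(self) -> None:
        self.centers = [tuple(int(c) for c in ctr) for ctr in self.centers]
        self.artifact_slices = [set(int(z) for z in s) for s in self.artifact_slices]
        if len(self.centers) != len(self.artifact_slices):
            raise ValueError("need one artifact-slice set per fiducial center")
        for ctr, sl in zip(self.centers, self.artifact_slices):
            if self.centers and not sl:
                raise ValueError(f"fiducial at {ctr} has no artifact slices")

    @property
    def all_artifact_slices(self) -> set[int]:
        out: set[int] = set()
        for s in self.artifact_slices:
            out |= s
        return out

    def rescaled(self, spacing_mm, target_mm: float) -> "FiducialAnnotation":
        """Map voxel coordinates onto a resampled ``target_mm`` isotropic grid."""
        sx, sy, sz = spacing_mm
        centers = [
            (round(x * sx / target_mm), round(y * sy / target_mm), round(z * sz / target_mm))
            for x, y, z in self.centers
        ]
        slices = []
        for s in self.artifact_slices:
            zz: set[int] = set()
            for z in s:
                lo = int(np.floor((z - 0.5) * sz / target_mm))
                hi = int(np.ceil((z + 0.5) * sz / target_mm))
                zz.update(range(max(lo, 0), hi + 1))
            slices.append(zz)
        return FiducialAnnotation(centers, slices)


@dataclass
class ArtifactMask:
    masked: np.ndarray  # 3D boolean grid of voxels to remove
    components: list[np.ndarray] = field(default_factory=list)  # per-fiducial masks
    threshold: tuple[float, float] = (0.0, 0.0)


def artifact_threshold(
    vol: ImageVolume, mask: RoiMask, ann: FiducialAnnotation
) -> tuple[float, float]:
    """Estimate the artifact intensity threshold from artifact-free slices.

    mu and sigma are computed over in-ROI voxels on axial slices not listed in
    any fiducial's artifact-slice set; the returned range is
    (mu - 3 sigma, mu + 3 sigma).
    """
    artifact_z = ann.all_artifact_slices
    roi_z = set(int(z) for z in np.unique(np.nonzero(mask.inside)[2]))
    clean_z = sorted(roi_z - artifact_z)
    if not clean_z:
        raise ValueError(
            "every ROI slice contains a fiducial artifact; supply a manual threshold"
        )
    sel = np.zeros(mask.shape, dtype=bool)
    sel[:, :, clean_z] = True
    values = vol.values[mask.inside & sel]
    mu = float(values.mean())
    sigma = float(values.std())
    return (mu - 3.0 * sigma, mu + 3.0 * sigma)


def build_artifact_mask(
    vol: ImageVolume,
    mask: RoiMask,
    ann: FiducialAnnotation,
    threshold: tuple[float, float],
    radius_mm: float = 5.0,
) -> ArtifactMask:
    """Construct the per-slice removal mask around each fiducial.

    On each artifact slice of each fiducial the mask unions (a) in-ROI pixels
    whose center lies within ``radius_mm`` of the fiducial (in-plane spacing),
    (b) in-ROI pixels outside the threshold range, and (c) the Bresenham line
    from each such distal pixel to the fiducial center, restricted to the ROI.
    """
    low, high = float(threshold[0]), float(threshold[1])
    if low > high:
        raise ValueError("threshold low must not exceed high")
    sx, sy = vol.spacing_mm[0], vol.spacing_mm[1]
    if radius_mm < min(sx, sy):
        warnings.warn(
            "artifact radius is below one pixel; the disk degenerates to the center pixel",
            stacklevel=2,
        )
    nx, ny, nz = vol.shape
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    components: list[np.ndarray] = []
    for (cx, cy, _cz), slices in zip(ann.centers, ann.artifact_slices):
        comp = np.zeros(vol.shape, dtype=bool)
        disk2d = ((gx - cx) * sx) ** 2 + ((gy - cy) * sy) ** 2 <= radius_mm**2
        for z in sorted(slices):
            if not (0 <= z < nz):
                continue
            roi2d = mask.inside[:, :, z]
            plane = disk2d & roi2d
            outliers = roi2d & ((vol.values[:, :, z] < low) | (vol.values[:, :, z] > high))
            plane |= outliers
            for ox, oy in zip(*np.nonzero(outliers)):
                rr, cc = bresenham_line(int(ox), int(oy), int(cx), int(cy))
                keep = roi2d[rr, cc]
                plane[rr[keep], cc[keep]] = True
            comp[:, :, z] = plane
        components.append(comp)
    masked = np.zeros(vol.shape, dtype=bool)
    for comp in components:
        masked |= comp
    return ArtifactMask(masked=masked, components=components, threshold=(low, high))


def apply_artifact_mask(mask: RoiMask, am: ArtifactMask) -> tuple[RoiMask, float]:
    """Remove masked voxels from the ROI; returns the reduced ROI and the
    fraction of ROI voxels removed."""
    if mask.shape != am.masked.shape:
        raise ValueError("mask shapes differ")
    keep = mask.inside & ~am.masked
    removed = mask.n_voxels - int(keep.sum())
    if not keep.any():
        raise ValueError("artifact mask removed the entire ROI")
    return RoiMask(keep), removed / mask.n_voxels


def save_fiducials(ann: FiducialAnnotation, path) -> None:
    payload = {
        "centers": [list(c) for c in ann.centers],
        "artifact_slices": [sorted(s) for s in ann.artifact_slices],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fiducials(path) -> FiducialAnnotation:
    with open(path) as fh:
        payload = json.load(fh)
    return FiducialAnnotation(
        [tuple(c) for c in payload["centers"]],
        [set(s) for s in payload["artifact_slices"]],
    )
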