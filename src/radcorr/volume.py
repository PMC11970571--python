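"""Core in-memory containers and NIfTI round-trip helpers.

The package works on plain scalar 3D grids with an explicit physical voxel
spacing.  Axes are ordered (x, y, z) with z the axial (slice) axis, matching
how the fiducial-artifact algorithm operates per axial slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "QuantizedRoi",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class RoiMask:
    """Binary region-of-interest mask aligned with an :class:`ImageVolume`."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if self.inside.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.inside.shape}")
        if not self.inside.any():
            raise ValueError("ROI mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    def volume_mm3(self, spacing_mm) -> float:
        return self.n_voxels * float(np.prod(spacing_mm))


@dataclass
class QuantizedRoi:
    """Gray levels 1..Ng on the (re-segmented) ROI, plus the quantizer codebook.

    ``levels`` is an integer grid valued 1..Ng on mask voxels and 0 elsewhere.
    ``n_levels`` is the nominal level count Ng; ``n_levels_effective`` may be
    smaller when the ROI holds fewer distinct intensities than Ng.
    """

    levels: np.ndarray
    mask: RoiMask
    n_levels: int
    codebook: np.ndarray
    value_range: tuple[float, float]
    n_levels_effective: int = 0
    n_iterations: int = 0
    mse_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        self.codebook = np.asarray(self.codebook, dtype=np.float64)
        inside = self.levels[self.mask.inside]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("levels outside 1..Ng inside the mask")
        if (self.levels[~self.mask.inside] != 0).any():
            raise ValueError("nonzero levels outside the mask")
        if not self.n_levels_effective:
            self.n_levels_effective = int(len(np.unique(inside)))


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def save_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing_mm))
    nib.save(img, str(path))


def load_volume(path, modality: str = "") -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asanyarray(img.dataobj).astype(np.float64), spacing, modality)


def save_mask(mask: RoiMask, spacing_mm, path) -> None:
    img = nib.Nifti1Image(mask.inside.astype(np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))


def load_mask(path) -> RoiMask:
    img = nib.load(str(path))
    return RoiMask(np.asanyarray(img.dataobj) > 0)
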