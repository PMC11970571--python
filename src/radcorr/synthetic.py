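"""Synthetic phantom cohorts with controllable cross-modality texture sharing.

Each phantom patient mimics the data layout of a prostate radiotherapy case:
three co-registered scalar volumes (a T2-weighted-MRI-like, a CT-like, and a
cone-beam-CT-like image), one ellipsoidal prostate-like ROI whose size varies
across patients, fiducial-seed annotations, and in-plane streak artifacts on
the two X-ray-like modalities.

The texture model is a latent Gaussian random field: per patient a shared
smooth field S and independent per-modality fields H_m are drawn (white noise
smoothed by a Gaussian kernel of width ``correlation_length_mm``), and the
noiseless modality image is

    f_m( sqrt(w) * S + sqrt(1 - w) * H_m ) * gain_m + offset_m,

where w is ``shared_weight`` (fraction of texture variance common to all
modalities) and f_m a monotone contrast transform (identity, negation to
emulate the T2-vs-CT contrast inversion, or a signed gamma curve).  Optional
volume coupling scales the combined field by exp(volume_coupling * z), with z
the patient's standardized log ROI volume, so that intensity-spread features
become volume-confounded when the coupling is switched on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as bresenham_line

from .fiducials import FiducialAnnotation, save_fiducials
from .volume import ImageVolume, RoiMask, save_mask, save_volume

__all__ = [
    "ModalityParams",
    "StreakParams",
    "CohortSpec",
    "PhantomPatient",
    "StreakTruth",
    "generate_cohort",
    "inject_fiducial_streaks",
    "write_cohort",
    "DEFAULT_MODALITIES",
]

TRANSFORMS = ("identity", "negate", "gamma")


@dataclass(frozen=True)
class ModalityParams:
    """Monotone contrast transform plus affine intensity scale of one modality.

    ``noise_sd`` is additive white noise in image units; ``gain`` maps the
    unit-variance latent field to image units, so gain is also the noiseless
    texture standard deviation.  ``has_streaks`` marks the X-ray-like
    modalities that receive fiducial streak artifacts.
    """

    transform: str = "identity"
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    gamma: float = 1.5
    has_streaks: bool = False

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        if self.transform == "identity":
            y = x
        elif self.transform == "negate":
            y = -x
        else:  # signed gamma curve, strictly increasing
            y = np.sign(x) * np.abs(x) ** self.gamma
        return self.gain * y + self.offset


@dataclass(frozen=True)
class StreakParams:
    """Streak artifact geometry: radial in-plane segments per fiducial.

    ``amplitude`` is in latent-field units and is scaled by each modality's
    gain at injection time; the default of 6 texture standard deviations makes
    streaks clearly supra-threshold against the 3-sigma artifact threshold,
    reproducing the regime where run-length and size-zone features are the
    artifact-sensitive ones.
    """

    n_streaks: int = 8
    length_mm: float = 12.0
    amplitude: float = 6.0

    def __post_init__(self) -> None:
        if self.n_streaks < 0 or self.length_mm < 0 or self.amplitude < 0:
            raise ValueError("streak parameters must be non-negative")


# Typical prostate: ellipsoid radii with median (22, 18, 20) mm give a median
# ROI volume of ~33 cm^3; sigma_log 0.15 per axis spreads volumes over roughly
# 15-70 cm^3 across a cohort, matching clinical variability.
DEFAULT_RADII_LOG_MEDIAN = (22.0, 18.0, 20.0)
DEFAULT_RADII_LOG_SIGMA = 0.15

DEFAULT_MODALITIES: dict[str, ModalityParams] = {
    "T2w": ModalityParams(transform="negate", gain=120.0, offset=450.0, noise_sd=12.0),
    "CT": ModalityParams(transform="identity", gain=25.0, offset=35.0, noise_sd=4.0, has_streaks=True),
    "CBCT": ModalityParams(transform="identity", gain=25.0, offset=35.0, noise_sd=8.0, has_streaks=True),
}


@dataclass(frozen=True)
class CohortSpec:
    """Stated world of a phantom cohort; identical specs (including the seed)
    generate bit-identical cohorts."""

    n_patients: int = 47
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    correlation_length_mm: float = 3.0
    shared_weight: float = 0.5
    modality_params: dict[str, ModalityParams] = field(
        default_factory=lambda: dict(DEFAULT_MODALITIES)
    )
    roi_radii_log_median_mm: tuple[float, float, float] = DEFAULT_RADII_LOG_MEDIAN
    roi_radii_log_sigma: float = DEFAULT_RADII_LOG_SIGMA
    volume_coupling: float = 0.0
    n_fiducials: int = 3
    streak_params: StreakParams = field(default_factory=StreakParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be three positive values, got {self.spacing_mm}")
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValueError("shared_weight must lie in [0, 1]")
        if not 0.0 <= self.volume_coupling <= 1.0:
            raise ValueError("volume_coupling must lie in [0, 1]")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")
        if any(r <= 0 for r in self.roi_radii_log_median_mm) or self.roi_radii_log_sigma <= 0:
            raise ValueError("ROI radii parameters must be positive")
        if self.n_fiducials < 0:
            raise ValueError("n_fiducials must be >= 0")
        if not self.modality_params:
            raise ValueError("at least one modality is required")


@dataclass
class StreakTruth:
    """Exact record of the voxels a streak injection altered."""

    voxels: np.ndarray  # (N, 3) int voxel coordinates (deduplicated)
    deltas: np.ndarray  # (N,) summed intensity change at each voxel

    @classmethod
    def empty(cls) -> "StreakTruth":
        return cls(np.zeros((0, 3), dtype=np.intp), np.zeros(0))


@dataclass
class PhantomPatient:
    patient_id: str
    volumes: dict[str, ImageVolume]
    mask: RoiMask
    fiducials: FiducialAnnotation
    truth: dict


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel, standardized over the grid."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="reflect")
    return (f - f.mean()) / f.std()


def _ellipsoid_mask(shape, spacing, radii_mm) -> np.ndarray:
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx = (axes[0] - center[0]) / radii_mm[0]
    yy = (axes[1] - center[1]) / radii_mm[1]
    zz = (axes[2] - center[2]) / radii_mm[2]
    return (
        xx[:, None, None] ** 2 + yy[None, :, None] ** 2 + zz[None, None, :] ** 2
    ) <= 1.0


def inject_fiducial_streaks(
    vol: ImageVolume,
    mask: RoiMask,
    fiducials: FiducialAnnotation,
    streak_params: StreakParams,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> tuple[ImageVolume, StreakTruth]:
    """Add in-plane radial streak segments around each fiducial center.

    Streaks alternate between bright and dark with intensity change
    ``streak_params.amplitude * amplitude_scale``; the fiducial center pixel
    itself receives a strong bright spike (the metal seed).  Returns the new
    volume and the exact set of altered voxels with their intensity deltas.
    A zero amplitude or an empty fiducial list returns the input unchanged
    with an empty truth set.
    """
    amp = streak_params.amplitude * amplitude_scale
    if amp == 0.0 or not fiducials.centers:
        return vol, StreakTruth.empty()
    for ctr in fiducials.centers:
        if not mask.inside[ctr]:
            raise ValueError(f"fiducial center {ctr} lies outside the ROI")
    rng = rng or np.random.default_rng()
    nx, ny, _nz = vol.shape
    sx, sy = vol.spacing_mm[0], vol.spacing_mm[1]
    values = vol.values.copy()
    hits: dict[tuple[int, int, int], float] = {}

    def _add(x: int, y: int, z: int, delta: float) -> None:
        values[x, y, z] += delta
        key = (x, y, z)
        hits[key] = hits.get(key, 0.0) + delta

    for (cx, cy, _cz), slices in zip(fiducials.centers, fiducials.artifact_slices):
        for z in sorted(slices):
            phase = rng.uniform(0, 2 * np.pi)
            _add(cx, cy, z, 3.0 * amp)
            for k in range(streak_params.n_streaks):
                theta = phase + 2 * np.pi * k / max(streak_params.n_streaks, 1)
                ex = cx + streak_params.length_mm * np.cos(theta) / sx
                ey = cy + streak_params.length_mm * np.sin(theta) / sy
                ex = int(np.clip(round(ex), 0, nx - 1))
                ey = int(np.clip(round(ey), 0, ny - 1))
                rr, cc = bresenham_line(cx, cy, ex, ey)
                sign = 1.0 if k % 2 == 0 else -1.0
                for x, y in zip(rr[1:], cc[1:]):  # skip the center pixel itself
                    _add(int(x), int(y), z, sign * amp)
    if hits:
        voxels = np.array(sorted(hits), dtype=np.intp)
        deltas = np.array([hits[tuple(v)] for v in voxels])
    else:
        voxels, deltas = np.zeros((0, 3), dtype=np.intp), np.zeros(0)
    return ImageVolume(values, vol.spacing_mm, vol.modality), StreakTruth(voxels, deltas)


def _place_fiducials(
    rng: np.random.Generator, mask: np.ndarray, n: int, min_sep_vox: float = 8.0
) -> list[tuple[int, int, int]]:
    # Erode toward the ROI core so centers sit well inside the mask.
    core = ndimage.binary_erosion(mask, iterations=2)
    if not core.any():
        core = mask
    cand = np.argwhere(core)
    centers: list[tuple[int, int, int]] = []
    for _ in range(200):
        if len(centers) == n:
            break
        pick = cand[rng.integers(cand.shape[0])]
        if all(np.linalg.norm(pick - np.array(c)) >= min_sep_vox for c in centers):
            centers.append(tuple(int(v) for v in pick))
    while len(centers) < n:  # give up on separation if the ROI is tiny
        pick = cand[rng.integers(cand.shape[0])]
        centers.append(tuple(int(v) for v in pick))
    return centers


def generate_cohort(spec: CohortSpec) -> list[PhantomPatient]:
    """Generate ``spec.n_patients`` phantom patients.

    A per-patient seed sequence spawned from the global seed makes each
    patient independently reproducible; the random draw order per patient is
    fixed (radii, shared field, per-modality fields in sorted modality order,
    noise, fiducials, streaks).
    """
    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = spec.spacing_mm
    sigma_vox = [spec.correlation_length_mm / s for s in spacing]
    w = spec.shared_weight
    modalities = sorted(spec.modality_params)
    # Analytic moments of log(volume) for the volume-coupling standardization.
    mu_logv = float(np.log(4 / 3 * np.pi) + sum(np.log(r) for r in spec.roi_radii_log_median_mm))
    sd_logv = spec.roi_radii_log_sigma * np.sqrt(3.0)
    half_extent = [((n - 1) / 2.0) * s for n, s in zip(shape, spacing)]

    patients: list[PhantomPatient] = []
    for p_idx, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        log_r = np.log(spec.roi_radii_log_median_mm) + spec.roi_radii_log_sigma * rng.standard_normal(3)
        radii = np.exp(log_r)
        radii = np.minimum(radii, [h - 1.0 for h in half_extent])  # keep ellipsoid on-grid
        inside = _ellipsoid_mask(shape, spacing, radii)
        if not inside.any():
            raise ValueError("drawn ROI ellipsoid contains no voxel; enlarge the grid")
        mask = RoiMask(inside)
        roi_volume = mask.volume_mm3(spacing)
        z_vol = (float(np.log(roi_volume)) - mu_logv) / sd_logv
        amplitude = float(np.exp(spec.volume_coupling * z_vol))

        shared = _smooth_unit_field(rng, shape, sigma_vox)
        combined: dict[str, np.ndarray] = {}
        for m in modalities:
            own = _smooth_unit_field(rng, shape, sigma_vox)
            combined[m] = amplitude * (np.sqrt(w) * shared + np.sqrt(1.0 - w) * own)
        volumes: dict[str, ImageVolume] = {}
        for m in modalities:
            params = spec.modality_params[m]
            img = params.apply(combined[m])
            if params.noise_sd > 0:
                img = img + params.noise_sd * rng.standard_normal(shape)
            volumes[m] = ImageVolume(img, spacing, modality=m)

        if spec.n_fiducials > 0:
            centers = _place_fiducials(rng, inside, spec.n_fiducials)
            roi_z = np.unique(np.nonzero(inside)[2])
            slices = []
            for _, _, cz in centers:
                zz = {int(z) for z in (cz - 1, cz, cz + 1) if z in roi_z}
                slices.append(zz or {int(cz)})
            fid = FiducialAnnotation(centers, slices)
        else:
            fid = FiducialAnnotation([], [])

        streak_truth: dict[str, StreakTruth] = {}
        for m in modalities:
            params = spec.modality_params[m]
            if params.has_streaks and spec.n_fiducials > 0:
                volumes[m], truth = inject_fiducial_streaks(
                    volumes[m], mask, fid, spec.streak_params, rng, amplitude_scale=params.gain
                )
            else:
                truth = StreakTruth.empty()
            streak_truth[m] = truth

        patients.append(
            PhantomPatient(
                patient_id=f"P{p_idx + 1:03d}",
                volumes=volumes,
                mask=mask,
                fiducials=fid,
                truth={
                    "radii_mm": tuple(float(r) for r in radii),
                    "roi_volume_mm3": roi_volume,
                    "z_log_volume": z_vol,
                    "texture_amplitude": amplitude,
                    "shared_roi_mean": float(shared[inside].mean()),
                    "shared_roi_var": float(shared[inside].var()),
                    "gains": {m: spec.modality_params[m].gain for m in modalities},
                    "streaks": streak_truth,
                },
            )
        )
    return patients


def clean_volume(patient: PhantomPatient, modality: str) -> ImageVolume:
    """Reconstruct the artifact-free image of a modality from the streak truth."""
    vol = patient.volumes[modality]
    truth: StreakTruth = patient.truth["streaks"][modality]
    values = vol.values.copy()
    if truth.voxels.size:
        values[truth.voxels[:, 0], truth.voxels[:, 1], truth.voxels[:, 2]] -= truth.deltas
    return ImageVolume(values, vol.spacing_mm, vol.modality)


def write_cohort(patients: list[PhantomPatient], out_dir) -> "pd.DataFrame":
    """Write volumes/masks as NIfTI, fiducials and truth as JSON, and return
    (and save) a manifest of file paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in patients:
        pdir = out / pat.patient_id
        pdir.mkdir(exist_ok=True)
        spacing = next(iter(pat.volumes.values())).spacing_mm
        mask_path = pdir / "mask.nii.gz"
        save_mask(pat.mask, spacing, mask_path)
        fid_path = pdir / "fiducials.json"
        save_fiducials(pat.fiducials, fid_path)
        truth_path = pdir / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(_truth_jsonable(pat.truth), fh)
        for m, vol in pat.volumes.items():
            vol_path = pdir / f"{m}.nii.gz"
            save_volume(vol, vol_path)
            rows.append(
                {
                    "patient_id": pat.patient_id,
                    "modality": m,
                    "volume": str(vol_path),
                    "mask": str(mask_path),
                    "fiducials": str(fid_path),
                    "truth": str(truth_path),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _truth_jsonable(truth: dict) -> dict:
    out = dict(truth)
    out["streaks"] = {
        m: {"voxels": t.voxels.tolist(), "deltas": t.deltas.tolist()}
        for m, t in truth["streaks"].items()
    }
    return out
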