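"""Scalar feature formulas evaluated on the texture matrices.

Gray levels enter every formula as their 1-based integer values.  Undefined
features (e.g. GLCM correlation on a flat ROI, skewness at zero variance,
busyness on a single-level ROI) are returned as NaN, never silently zeroed.
"""

from __future__ import annotations

import numpy as np

from .matrices import NgtdmParts

__all__ = [
    "features_glcm",
    "features_glrlm",
    "features_glszm",
    "features_ngtdm",
    "features_intensity",
    "N_DIRECTIONS",
    "NGTDM_EPS",
]

#: Merged-direction count used by the run-percentage convention
#: RP = n_runs / (n_voxels * 13).
N_DIRECTIONS = 13

#: Stabilizer in coarseness/strength denominators; a flat ROI reports the
#: capped sentinel coarseness 1/NGTDM_EPS.
NGTDM_EPS = 1e-6


def features_glcm(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu = float((ii * p).sum())  # symmetric: row and column means coincide
    var = float(((ii - mu) ** 2 * p).sum())
    out = {
        "GLCM_Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM_Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "GLCM_SumAverage": float(((ii + jj) * p).sum()),
        "GLCM_Variance": var,
    }
    nz = p[p > 0]
    out["GLCM_Entropy"] = float(-(nz * np.log2(nz)).sum())
    if var > 0:
        out["GLCM_Correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / var)
    else:
        out["GLCM_Correlation"] = np.nan
    return out


def _run_zone_common(m: np.ndarray, n_voxels: int, prefix: str, pct_name: str, denom_pct: float) -> dict[str, float]:
    ng, rmax = m.shape
    g = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    r = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    ns = m.sum()
    p = m / ns
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_g = float((g[:, 0] * row / ns).sum())
    mu_r = float((r[0, :] * col / ns).sum())
    short, long_, low, high = ("SRE", "LRE", "LGRE", "HGRE") if prefix == "GLRLM" else ("SZE", "LZE", "LGZE", "HGZE")
    sl = ("SRLGE", "SRHGE", "LRLGE", "LRHGE") if prefix == "GLRLM" else ("SZLGE", "SZHGE", "LZLGE", "LZHGE")
    var_name = "RLV" if prefix == "GLRLM" else "ZSV"
    nonuni = "RLN" if prefix == "GLRLM" else "ZSN"
    return {
        f"{prefix}_{short}": float((m / r**2).sum() / ns),
        f"{prefix}_{long_}": float((m * r**2).sum() / ns),
        f"{prefix}_{low}": float((m / g**2).sum() / ns),
        f"{prefix}_{high}": float((m * g**2).sum() / ns),
        f"{prefix}_{sl[0]}": float((m / (g**2 * r**2)).sum() / ns),
        f"{prefix}_{sl[1]}": float((m * g**2 / r**2).sum() / ns),
        f"{prefix}_{sl[2]}": float((m * r**2 / g**2).sum() / ns),
        f"{prefix}_{sl[3]}": float((m * g**2 * r**2).sum() / ns),
        f"{prefix}_GLN": float((row**2).sum() / ns),
        f"{prefix}_{nonuni}": float((col**2).sum() / ns),
        f"{prefix}_{pct_name}": float(ns / denom_pct),
        f"{prefix}_GLV": float(((g[:, 0] - mu_g) ** 2 * row / ns).sum()),
        f"{prefix}_{var_name}": float(((r[0, :] - mu_r) ** 2 * col / ns).sum()),
    }


def features_glrlm(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    """13 run-length features; RP uses the merged-direction convention
    n_runs / (n_voxels * 13)."""
    return _run_zone_common(m, n_voxels, "GLRLM", "RP", n_voxels * N_DIRECTIONS)


def features_glszm(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_common(m, n_voxels, "GLSZM", "ZP", float(n_voxels))


def features_ngtdm(parts: NgtdmParts, eps: float = NGTDM_EPS) -> dict[str, float]:
    """Amadasun-King busyness, coarseness, complexity, contrast, strength."""
    occ = parts.occupied
    p = parts.p_i[occ]
    s = parts.s_i[occ]
    i = (occ + 1).astype(np.float64)
    n = parts.n_valid
    ngp = occ.size
    out: dict[str, float] = {}
    ps = float((p * s).sum())
    out["NGTDM_Coarseness"] = 1.0 / (eps + ps)
    if ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        si, sj = np.meshgrid(s, s, indexing="ij")
        out["NGTDM_Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / n
        )
        busy_den = float(np.abs(ii * pi - jj * pj).sum())
        out["NGTDM_Busyness"] = ps / busy_den if busy_den > 0 else np.nan
        out["NGTDM_Complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (n * (pi + pj))).sum()
        )
        out["NGTDM_Strength"] = float(((pi + pj) * (ii - jj) ** 2).sum()) / (eps + float(s.sum()))
    else:
        out["NGTDM_Contrast"] = 0.0
        out["NGTDM_Busyness"] = np.nan
        out["NGTDM_Complexity"] = 0.0
        out["NGTDM_Strength"] = 0.0
    return out


def features_intensity(values: np.ndarray) -> dict[str, float]:
    """Population variance, skewness, and raw (non-excess) kurtosis of the raw
    re-segmented ROI intensities."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("intensity statistics need at least 2 voxels")
    if np.ptp(values) == 0:  # flat ROI: variance exactly zero, not rounding dust
        return {"IS_Variance": 0.0, "IS_Skewness": np.nan, "IS_Kurtosis": np.nan}
    mu = values.mean()
    centered = values - mu
    var = float((centered**2).mean())
    out = {"IS_Variance": var}
    if var > 0:
        sigma = np.sqrt(var)
        out["IS_Skewness"] = float((centered**3).mean() / sigma**3)
        out["IS_Kurtosis"] = float((centered**4).mean() / sigma**4)
    else:
        out["IS_Skewness"] = np.nan
        out["IS_Kurtosis"] = np.nan
    return out
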