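"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain loops straight from the textbook
definitions, deliberately sharing no code with the package: matrix builders
enumerate voxel pairs / runs / zones / neighborhoods one by one, and the
feature formulas are evaluated with explicit sums.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
OFFSETS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def oracle_glcm(levels, mask, ng):
    """Pair-enumeration GLCM: both orderings of the 13 offsets, normalized."""
    shape = levels.shape
    counts = np.zeros((ng, ng))
    for p in zip(*np.nonzero(mask)):
        for d in OFFSETS_13:
            for sgn in (1, -1):
                q = tuple(c + sgn * s for c, s in zip(p, d))
                if _in(shape, q) and mask[q]:
                    counts[levels[p] - 1, levels[q] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def oracle_glcm_single_direction(levels, mask, ng, d):
    """Counts (not normalized) for one offset, both orderings."""
    shape = levels.shape
    counts = np.zeros((ng, ng))
    for p in zip(*np.nonzero(mask)):
        for sgn in (1, -1):
            q = tuple(c + sgn * s for c, s in zip(p, d))
            if _in(shape, q) and mask[q]:
                counts[levels[p] - 1, levels[q] - 1] += 1
    return counts


def oracle_glrlm(levels, mask, ng):
    """Scanline enumeration of maximal same-level runs along all 13 offsets."""
    shape = levels.shape
    lv = np.where(mask, levels, 0)
    runs = []  # (level, length)
    for d in OFFSETS_13:
        for start in product(*(range(n) for n in shape)):
            prev = tuple(c - s for c, s in zip(start, d))
            if _in(shape, prev):
                continue  # not a line origin
            seq = []
            p = start
            while _in(shape, p):
                seq.append(lv[p])
                p = tuple(c + s for c, s in zip(p, d))
            i = 0
            while i < len(seq):
                if seq[i] == 0:
                    i += 1
                    continue
                j = i
                while j < len(seq) and seq[j] == seq[i]:
                    j += 1
                runs.append((seq[i], j - i))
                i = j
    rmax = max((r for _, r in runs), default=1)
    m = np.zeros((ng, rmax))
    for g, r in runs:
        m[g - 1, r - 1] += 1
    return m


def oracle_glszm(levels, mask, ng):
    """Flood-fill enumeration of 26-connected equal-level zones."""
    shape = levels.shape
    lv = np.where(mask, levels, 0)
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in zip(*np.nonzero(lv)):
        if seen[p]:
            continue
        g = lv[p]
        stack = [p]
        seen[p] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(c + s for c, s in zip(cur, d))
                if _in(shape, q) and not seen[q] and lv[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    zmax = max((z for _, z in zones), default=1)
    m = np.zeros((ng, zmax))
    for g, z in zones:
        m[g - 1, z - 1] += 1
    return m


def oracle_ngtdm(levels, mask, ng):
    """Per-voxel 26-neighborhood enumeration; returns (p_i, s_i, n_i, n_valid)."""
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    n_valid = 0
    for p in zip(*np.nonzero(mask)):
        nb = []
        for d in OFFSETS_26:
            q = tuple(c + s for c, s in zip(p, d))
            if _in(shape, q) and mask[q]:
                nb.append(levels[q])
        if not nb:
            continue
        n_valid += 1
        g = levels[p]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(nb) / len(nb))
    p_i = n_i / n_valid if n_valid else n_i
    return p_i, s_i, n_i, n_valid


# ---------------------------------------------------------------- features

def oracle_glcm_features(p):
    ng = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out = {
        "GLCM_Contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM_Dissimilarity": sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM_Energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "GLCM_Entropy": -sum(
            p[i, j] * np.log2(p[i, j]) for i in range(ng) for j in range(ng) if p[i, j] > 0
        ),
        "GLCM_Homogeneity": sum(
            p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "GLCM_SumAverage": sum((i + j + 2) * p[i, j] for i in range(ng) for j in range(ng)),
        "GLCM_Variance": var,
    }
    if var > 0:
        out["GLCM_Correlation"] = (
            sum((i + 1 - mu) * (j + 1 - mu) * p[i, j] for i in range(ng) for j in range(ng)) / var
        )
    else:
        out["GLCM_Correlation"] = np.nan
    return out


def _oracle_rl_sz_features(m, n_voxels, prefix, names, pct_denom):
    ng, rmax = m.shape
    ns = m.sum()
    out = {}
    keys = ["S_E", "L_E", "LG_E", "HG_E", "S_LG", "S_HG", "L_LG", "L_HG"]
    weights = {
        "S_E": lambda g, r: 1 / r**2,
        "L_E": lambda g, r: r**2,
        "LG_E": lambda g, r: 1 / g**2,
        "HG_E": lambda g, r: g**2,
        "S_LG": lambda g, r: 1 / (g**2 * r**2),
        "S_HG": lambda g, r: g**2 / r**2,
        "L_LG": lambda g, r: r**2 / g**2,
        "L_HG": lambda g, r: g**2 * r**2,
    }
    for key, name in zip(keys, names[:8]):
        out[f"{prefix}_{name}"] = (
            sum(weights[key](g + 1, r + 1) * m[g, r] for g in range(ng) for r in range(rmax)) / ns
        )
    out[f"{prefix}_GLN"] = sum(m[g, :].sum() ** 2 for g in range(ng)) / ns
    out[f"{prefix}_{names[9]}"] = sum(m[:, r].sum() ** 2 for r in range(rmax)) / ns
    out[f"{prefix}_{names[10]}"] = ns / pct_denom
    mu_g = sum((g + 1) * m[g, :].sum() for g in range(ng)) / ns
    out[f"{prefix}_GLV"] = sum((g + 1 - mu_g) ** 2 * m[g, :].sum() for g in range(ng)) / ns
    mu_r = sum((r + 1) * m[:, r].sum() for r in range(rmax)) / ns
    out[f"{prefix}_{names[12]}"] = sum((r + 1 - mu_r) ** 2 * m[:, r].sum() for r in range(rmax)) / ns
    return out


def oracle_glrlm_features(m, n_voxels):
    names = ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
             "GLN", "RLN", "RP", "GLV", "RLV"]
    return _oracle_rl_sz_features(m, n_voxels, "GLRLM", names, n_voxels * 13)


def oracle_glszm_features(m, n_voxels):
    names = ["SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
             "GLN", "ZSN", "ZP", "GLV", "ZSV"]
    return _oracle_rl_sz_features(m, n_voxels, "GLSZM", names, n_voxels)


def oracle_ngtdm_features(p_i, s_i, n_valid, eps=1e-6):
    occ = [i for i in range(len(p_i)) if p_i[i] > 0]
    ngp = len(occ)
    ps = sum(p_i[i] * s_i[i] for i in occ)
    out = {"NGTDM_Coarseness": 1.0 / (eps + ps)}
    if ngp > 1:
        out["NGTDM_Contrast"] = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1))
            * sum(s_i[i] for i in occ)
            / n_valid
        )
        den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ)
        out["NGTDM_Busyness"] = ps / den if den > 0 else np.nan
        out["NGTDM_Complexity"] = sum(
            abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (n_valid * (p_i[i] + p_i[j]))
            for i in occ
            for j in occ
        )
        out["NGTDM_Strength"] = sum(
            (p_i[i] + p_i[j]) * (i - j) ** 2 for i in occ for j in occ
        ) / (eps + sum(s_i[i] for i in occ))
    else:
        out.update(NGTDM_Contrast=0.0, NGTDM_Busyness=np.nan, NGTDM_Complexity=0.0,
                   NGTDM_Strength=0.0)
    return out


def oracle_intensity_features(values):
    values = np.asarray(values, dtype=float)
    mu = values.mean()
    var = ((values - mu) ** 2).mean()
    out = {"IS_Variance": var}
    if var > 0:
        out["IS_Skewness"] = ((values - mu) ** 3).mean() / var**1.5
        out["IS_Kurtosis"] = ((values - mu) ** 4).mean() / var**2
    else:
        out["IS_Skewness"] = np.nan
        out["IS_Kurtosis"] = np.nan
    return out


def oracle_all_features(levels, mask, ng, raw_values, eps=1e-6):
    """Full 42-feature vector with volume normalization, all from the oracles."""
    n_vox = int(mask.sum())
    out = {}
    glcm = oracle_glcm(levels, mask, ng)
    if glcm.sum() > 0:
        out.update(oracle_glcm_features(glcm))
    else:
        out.update({k: np.nan for k in oracle_glcm_features(np.array([[1.0]]))})
    out.update(oracle_glrlm_features(oracle_glrlm(levels, mask, ng), n_vox))
    out.update(oracle_glszm_features(oracle_glszm(levels, mask, ng), n_vox))
    p_i, s_i, n_i, n_valid = oracle_ngtdm(levels, mask, ng)
    if n_valid:
        out.update(oracle_ngtdm_features(p_i, s_i, n_valid, eps))
    else:
        out.update(NGTDM_Coarseness=np.nan, NGTDM_Contrast=np.nan, NGTDM_Busyness=np.nan,
                   NGTDM_Complexity=np.nan, NGTDM_Strength=np.nan)
    out.update(oracle_intensity_features(raw_values))
    # volume normalization
    v = float(n_vox)
    for name in ("GLRLM_GLN", "GLRLM_RLN", "GLSZM_GLN", "GLSZM_ZSN"):
        out[name] = out[name] / v
    out["NGTDM_Strength"] = out["NGTDM_Strength"] * v
    if n_valid:
        occ = [i for i in range(ng) if p_i[i] > 0]
        num = sum(p_i[i] * s_i[i] / n_i[i] for i in occ)
        out["NGTDM_Coarseness"] = 1.0 / (eps + num)
        den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ)
        out["NGTDM_Busyness"] = num / den if den > 0 else np.nan
    return out


# ------------------------------------------------------------- statistics

def rankdata_average(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    """Rank-then-Pearson with average ranks."""
    rx = rankdata_average(x)
    ry = rankdata_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def oracle_bh(p):
    """Hand step-up Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def exact_permutation_spearman_p(x, y):
    """Two-sided exact permutation p-value of Spearman rho (no ties, n <= 8)."""
    n = len(x)
    rho_obs = abs(oracle_spearman(x, y))
    ranks_x = rankdata_average(x)
    perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
    rx = ranks_x - ranks_x.mean()
    ry = perms - perms.mean(axis=1, keepdims=True)
    rhos = (ry @ rx) / np.sqrt((rx**2).sum() * (ry**2).sum(axis=1))
    return float(np.mean(np.abs(rhos) >= rho_obs - 1e-12))


def equal_width_quantize_mse(values, low, high, n_bins):
    """Within-bin MSE of plain equal-width binning (Lloyd's competitor)."""
    values = np.asarray(values, dtype=float)
    width = (high - low) / n_bins
    idx = np.clip(((values - low) / width).astype(int), 0, n_bins - 1)
    mse = 0.0
    for b in range(n_bins):
        sel = values[idx == b]
        if len(sel):
            mse += ((sel - sel.mean()) ** 2).sum()
    return mse / len(values)


def disk_pixel_count(radius_mm, sx, sy, extent=40):
    """Brute-force count of pixels whose center lies within radius of (0,0)."""
    count = 0
    for i in range(-extent, extent + 1):
        for j in range(-extent, extent + 1):
            if (i * sx) ** 2 + (j * sy) ** 2 <= radius_mm**2:
                count += 1
    return count
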