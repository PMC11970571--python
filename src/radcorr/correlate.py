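"""Cross-modality Spearman correlation study.

The feature table is a patients x (modality, feature) DataFrame.  The analysis
computes the absolute Spearman correlation |rho| for every unordered column
pair (the matrix diagonal is trivially 1 and excluded), applies one pooled
Benjamini-Hochberg adjustment to the upper-triangle p-values, and classifies
each pair as intramodality, intermodality same-feature, or intermodality
cross-feature.  Features whose |rho| with same-modality ROI volume exceeds a
threshold (default 0.75) are removed beforehand to avoid volume confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features.registry import VOLUME_FEATURE, family_of

__all__ = [
    "spearman_abs",
    "bh_adjust",
    "volume_filter",
    "build_correlation_report",
    "summarize",
    "paired_ttest_masked",
    "CorrelationReport",
    "CLASS_INTRA",
    "CLASS_INTER_SAME",
    "CLASS_INTER_CROSS",
]

CLASS_INTRA = "intramodality"
CLASS_INTER_SAME = "intermodality_same_rf"
CLASS_INTER_CROSS = "intermodality_cross_rf"


def spearman_abs(x, y) -> tuple[float, float, int]:
    """Absolute average-rank Spearman correlation with its t-approximation p.

    Missing values are handled pairwise-complete.  Returns
    (|rho|, p_raw, n_complete).  Raises ``ValueError`` when fewer than three
    complete pairs remain or either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("zero rank variance")
    res = stats.spearmanr(xs, ys)
    rho = float(res.statistic)
    if not np.isfinite(rho):
        raise ValueError("Spearman correlation undefined")
    return abs(rho), float(res.pvalue), n


def bh_adjust(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags
    (adjusted p < alpha)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


@dataclass
class CorrelationReport:
    pairs: pd.DataFrame  # modality_a, feature_a, modality_b, feature_b, abs_rho, p_raw, p_adj, significant, n, class
    alpha: float
    dropped_pairs: list = field(default_factory=list)  # undefined pairs (zero rank variance etc.)
    volume_corr: pd.DataFrame | None = None
    dropped_for_volume: list = field(default_factory=list)


def _pair_class(mod_a: str, feat_a: str, mod_b: str, feat_b: str) -> str:
    if mod_a == mod_b:
        return CLASS_INTRA
    if feat_a == feat_b:
        return CLASS_INTER_SAME
    return CLASS_INTER_CROSS


def volume_filter(
    table: pd.DataFrame,
    threshold: float = 0.75,
    volume_feature: str = VOLUME_FEATURE,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.DataFrame]:
    """Drop features whose |Spearman| with same-modality ROI volume exceeds
    ``threshold``.

    Returns the filtered table (volume columns removed, kept for reporting in
    the returned ``volume_corr`` frame), the list of dropped (modality,
    feature) columns, and the per-column volume correlations R_V.
    """
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("feature table needs (modality, feature) MultiIndex columns")
    records = []
    dropped: list[tuple[str, str]] = []
    keep_cols = []
    for mod, feat in table.columns:
        if feat == volume_feature:
            continue
        vol_col = (mod, volume_feature)
        if vol_col not in table.columns:
            raise ValueError(f"no volume column for modality {mod!r}")
        try:
            rv, p, n = spearman_abs(table[(mod, feat)], table[vol_col])
        except ValueError:
            records.append({"modality": mod, "feature": feat, "r_volume": np.nan, "dropped": False})
            keep_cols.append((mod, feat))
            continue
        drop = rv > threshold
        records.append({"modality": mod, "feature": feat, "r_volume": rv, "dropped": drop})
        if drop:
            dropped.append((mod, feat))
        else:
            keep_cols.append((mod, feat))
    volume_corr = pd.DataFrame(records)
    return table[keep_cols], dropped, volume_corr


def build_correlation_report(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationReport:
    """All upper-triangle pairwise |rho| with one pooled BH adjustment.

    Pairs whose correlation is undefined (zero rank variance, too few complete
    observations) are excluded from the BH family and listed in
    ``dropped_pairs``.
    """
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("feature table needs (modality, feature) MultiIndex columns")
    cols = list(table.columns)
    rows = []
    dropped = []
    for (ma, fa), (mb, fb) in combinations(cols, 2):
        try:
            rho, p, n = spearman_abs(table[(ma, fa)], table[(mb, fb)])
        except ValueError as exc:
            dropped.append(((ma, fa), (mb, fb), str(exc)))
            continue
        rows.append(
            {
                "modality_a": ma,
                "feature_a": fa,
                "modality_b": mb,
                "feature_b": fb,
                "abs_rho": rho,
                "p_raw": p,
                "n": n,
                "class": _pair_class(ma, fa, mb, fb),
            }
        )
    pairs = pd.DataFrame(rows)
    if len(pairs):
        p_adj, sig = bh_adjust(pairs["p_raw"].to_numpy(), alpha)
        pairs["p_adj"] = p_adj
        pairs["significant"] = sig
    else:
        pairs["p_adj"] = pd.Series(dtype=float)
        pairs["significant"] = pd.Series(dtype=bool)
    return CorrelationReport(pairs=pairs, alpha=alpha, dropped_pairs=dropped)


def _group_key(row) -> str:
    if row["class"] == CLASS_INTRA:
        return row["modality_a"]
    mods = sorted([row["modality_a"], row["modality_b"]])
    return f"{mods[0]}-vs-{mods[1]}"


def summarize(
    report: CorrelationReport,
    thresholds: tuple[float, ...] = (0.75, 0.85, 0.95),
    bin_width: float = 0.05,
) -> dict:
    """Per comparison class and modality (or modality pair): the histogram of
    significant |rho|, the share of significant pairs, the share of significant
    pairs at or above each threshold, and the histogram mode bin center.

    Significance uses the BH-adjusted p (< alpha).
    """
    pairs = report.pairs
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    out: dict = {"alpha": report.alpha, "bin_edges": edges.tolist(), "classes": {}}
    if not len(pairs):
        return out
    pairs = pairs.assign(group=pairs.apply(_group_key, axis=1))
    for klass, by_class in pairs.groupby("class"):
        class_entry: dict = {}
        for group, sub in by_class.groupby("group"):
            sig = sub[sub["significant"]]
            counts, _ = np.histogram(sig["abs_rho"].to_numpy(), bins=edges)
            entry = {
                "n_pairs": int(len(sub)),
                "n_significant": int(len(sig)),
                "pct_significant": 100.0 * len(sig) / len(sub),
                "pct_at_or_above": {
                    str(t): (100.0 * float((sig["abs_rho"] >= t).mean()) if len(sig) else 0.0)
                    for t in thresholds
                },
                "hist_counts": counts.tolist(),
            }
            if counts.sum() > 0:
                mode_bin = int(np.argmax(counts))
                entry["mode_bin_center"] = float((edges[mode_bin] + edges[mode_bin + 1]) / 2)
            else:
                entry["mode_bin_center"] = None
            class_entry[group] = entry
        out["classes"][klass] = class_entry
    return out


def paired_ttest_masked(
    fv_masked: pd.DataFrame, fv_unmasked: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided paired t-test per feature between two extraction conditions
    (e.g. with and without the artifact mask applied), plus the Spearman
    correlation between conditions.

    Both frames are patients x features with identical indexes and columns.
    Zero-variance differences are flagged with p = 1.
    """
    if not fv_masked.columns.equals(fv_unmasked.columns) or not fv_masked.index.equals(
        fv_unmasked.index
    ):
        raise ValueError("the two feature tables must share patients and features")
    if len(fv_masked) < 2:
        raise ValueError("paired t-test needs at least 2 patients")
    rows = []
    for col in fv_masked.columns:
        a = fv_masked[col].to_numpy(dtype=float)
        b = fv_unmasked[col].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        feat = col if isinstance(col, str) else col[-1]
        rec = {"feature": feat, "family": _safe_family(feat), "n": int(ok.sum())}
        if ok.sum() < 2:
            rec.update(t=np.nan, p=np.nan, spearman_r=np.nan, degenerate=True)
        else:
            d = a[ok] - b[ok]
            if np.allclose(d, d[0]) and np.ptp(d) == 0 and d[0] == 0:
                rec.update(t=0.0, p=1.0, degenerate=True)
            elif np.ptp(d) == 0:
                # constant nonzero shift: t is infinite in the limit
                rec.update(t=np.inf if d[0] > 0 else -np.inf, p=0.0, degenerate=True)
            else:
                t, p = stats.ttest_rel(a[ok], b[ok])
                rec.update(t=float(t), p=float(p), degenerate=False)
            rs = stats.spearmanr(a[ok], b[ok]).statistic
            rec["spearman_r"] = float(rs) if np.isfinite(rs) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def _safe_family(feature: str) -> str:
    try:
        return family_of(feature)
    except KeyError:
        return ""
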