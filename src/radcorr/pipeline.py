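"""End-to-end driver: simulate -> preprocess -> artifact-mask -> extract ->
correlate -> power, communicating through files so each stage is independently
inspectable and the whole run is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlate import build_correlation_report, summarize, volume_filter
from .features import extract_all, registry
from .fiducials import (
    apply_artifact_mask,
    artifact_threshold,
    build_artifact_mask,
    load_fiducials,
)
from .power import PowerSpec, power_correlation
from .preprocess import collewet_resegment, lloyd_quantize, resample_isotropic
from .synthetic import CohortSpec, generate_cohort, write_cohort
from .volume import load_mask, load_volume

__all__ = ["PipelineConfig", "run_pipeline", "extract_features_table", "table_from_tidy"]


@dataclass
class PipelineConfig:
    """Analysis settings; the defaults are the study's stated ones: 64
    quantization bins, 1 mm isotropic grid, 5 mm artifact radius, alpha 0.05,
    volume-correlation filter at 0.75."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    bins: int = 64
    target_mm: float = 1.0
    artifact_radius_mm: float = 5.0
    alpha: float = 0.05
    volume_threshold: float = 0.75
    power_alpha: float = 4.0e-4
    power_rhos: tuple[float, ...] = (0.3, 0.75)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _process_case(
    vol, mask, fid, config: PipelineConfig, case_label: str
) -> tuple[dict[str, float], dict]:
    """Preprocess one (patient, modality) volume and extract its features."""
    log: dict = {"case": case_label}
    vol_r, mask_r = resample_isotropic(vol, mask, config.target_mm, case_id=case_label)
    roi = mask_r
    if fid is not None and fid.centers and vol.modality in _STREAK_MODALITIES:
        fid_r = fid.rescaled(vol.spacing_mm, config.target_mm)
        thr = artifact_threshold(vol_r, roi, fid_r)
        am = build_artifact_mask(vol_r, roi, fid_r, thr, config.artifact_radius_mm)
        roi, reduction = apply_artifact_mask(roi, am)
        log["artifact_threshold"] = thr
        log["roi_reduction_fraction"] = reduction
    cw = collewet_resegment(vol_r, roi)
    log.update(
        collewet_mean=cw.mean,
        collewet_std=cw.std,
        collewet_removed=cw.n_removed,
        collewet_degenerate=cw.degenerate,
    )
    q = lloyd_quantize(vol_r, cw.mask, cw.value_range, config.bins)
    log["lloyd_iterations"] = q.n_iterations
    log["effective_levels"] = q.n_levels_effective
    return extract_all(q, vol_r), log


_STREAK_MODALITIES = {"CT", "CBCT"}


def extract_features_table(manifest: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Run preprocessing + extraction for every manifest row; returns the tidy
    feature frame and the per-case preprocessing logs."""
    tidy_rows = []
    logs = []
    meta = {f.name: f for f in registry.FEATURES}
    for _, row in manifest.iterrows():
        vol = load_volume(row["volume"], modality=row["modality"])
        mask = load_mask(row["mask"])
        fid = load_fiducials(row["fiducials"]) if row.get("fiducials") else None
        features, log = _process_case(vol, mask, fid, config, f"{row['patient_id']}/{row['modality']}")
        logs.append(log)
        for name, value in features.items():
            fdef = meta.get(name)
            tidy_rows.append(
                {
                    "patient_id": row["patient_id"],
                    "modality": row["modality"],
                    "feature": name,
                    "family": fdef.family if fdef else "Geometry",
                    "ibsi_code": fdef.ibsi_code if fdef else "",
                    "vn_type": fdef.vn_type if fdef else 0,
                    "value": value,
                    "defined": bool(np.isfinite(value)),
                }
            )
    return pd.DataFrame(tidy_rows), logs


def table_from_tidy(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy feature frame to patients x (modality, feature)."""
    wide = tidy.pivot_table(
        index="patient_id", columns=["modality", "feature"], values="value", aggfunc="first"
    )
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["modality", "feature"])
    return wide


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full study on a synthetic cohort; every stage output is
    written under ``out_dir`` and re-running with the same config reproduces
    all CSV outputs bit-identically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patients = generate_cohort(config.cohort)
    manifest = write_cohort(patients, out / "cohort")

    tidy, logs = extract_features_table(manifest, config)
    features_csv = out / "features.csv"
    tidy.to_csv(features_csv, index=False)
    with open(out / "preprocess_log.json", "w") as fh:
        json.dump(_jsonable(logs), fh, indent=1)

    table = table_from_tidy(tidy)
    filtered, dropped, volume_corr = volume_filter(table, config.volume_threshold)
    volume_corr.to_csv(out / "volume_correlations.csv", index=False)
    report = build_correlation_report(filtered, config.alpha)
    report.volume_corr = volume_corr
    report.dropped_for_volume = dropped
    report.pairs.to_csv(out / "pairs.csv", index=False)
    summary = summarize(report)
    summary["dropped_for_volume"] = [list(d) for d in dropped]
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1)

    n = config.cohort.n_patients
    power = {
        str(rho): power_correlation(PowerSpec(n, rho, config.power_alpha, 2))
        for rho in config.power_rhos
    } if n >= 4 else {}
    with open(out / "power.json", "w") as fh:
        json.dump({"n": n, "alpha": config.power_alpha, "tails": 2, "power": power}, fh, indent=1)

    provenance = {
        "radcorr_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.cohort.seed,
        "config_hash": config.config_hash(),
        "config": _jsonable(asdict(config)),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)

    return {
        "manifest": manifest,
        "features_csv": features_csv,
        "table": table,
        "report": report,
        "summary": summary,
        "power": power,
        "out_dir": out,
    }
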