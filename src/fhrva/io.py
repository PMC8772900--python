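"""Plain-text readers and writers for records, tables and reports.

All artifacts are human-readable text: one CSV per FHR record
(``time_s, fhr_bpm`` with empty fields for signal loss), a corpus
metadata CSV, ground truth in YAML, feature and reduced-feature tables
as CSV with a fixed schema, and structured text reports for quality
gating, the block PCA and the fitted models.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .block_reduction import BlockPCAResult, REDUCED_COLUMNS, eigenvalue_spectrum
from .linear_features import FEATURE_NAMES
from .preprocessing import FHRRecord, QualityReport
from .synthetic_ctg import GroundTruth

__all__ = [
    "write_record",
    "read_record",
    "write_ground_truth",
    "write_feature_table",
    "read_feature_table",
    "write_reduced_table",
    "write_quality_report",
    "write_pca_report",
    "write_model_report",
    "write_surfaces",
]

FEATURE_TABLE_COLUMNS = ("record_id", *FEATURE_NAMES, "accel_count")


def write_record(record: FHRRecord, path: str | pathlib.Path) -> pathlib.Path:
    """Write one record as a two-column CSV (missing samples empty)."""
    path = pathlib.Path(path)
    t = np.arange(record.fhr.size) / record.sampling_rate
    pd.DataFrame({"time_s": t, "fhr_bpm": record.fhr}).to_csv(path, index=False)
    return path


def read_record(
    path: str | pathlib.Path,
    record_id: str | None = None,
    week: int | None = None,
    accel_count_target: int | None = None,
    visually_flagged: bool = False,
) -> FHRRecord:
    """Read a record CSV; the sampling rate is recovered from the time grid."""
    path = pathlib.Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "fhr_bpm"]:
        raise ValueError(f"{path}: expected columns ['time_s', 'fhr_bpm'], got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: record too short to infer sampling rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time grid is not evenly sampled")
    return FHRRecord(
        record_id=record_id or path.stem,
        fhr=df["fhr_bpm"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt[0],
        week=week,
        accel_count_target=accel_count_target,
        visually_flagged=visually_flagged,
    )


def write_ground_truth(
    truths: dict[str, GroundTruth], path: str | pathlib.Path
) -> pathlib.Path:
    """Ground truth per record as structured key-value text (YAML).

    Only compact fields are stored (counts, intervals, artifact indices);
    the full clean/floatingline series stay in memory or can be
    regenerated from the seeded configuration.
    """
    path = pathlib.Path(path)
    payload = {
        rid: {
            "accel_count": int(t.accel_count),
            "accel_intervals": [[float(a), float(b)] for a, b in t.accel_intervals],
            "injected_outlier_idx": [int(i) for i in t.injected_outlier_idx],
            "injected_gap_intervals": [[float(a), float(b)] for a, b in t.injected_gap_intervals],
        }
        for rid, t in truths.items()
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def write_feature_table(table: pd.DataFrame, path: str | pathlib.Path) -> pathlib.Path:
    """Write the per-record feature table (19 features + id + target)."""
    _check_feature_schema(table.columns, "feature table")
    path = pathlib.Path(path)
    table.loc[:, list(FEATURE_TABLE_COLUMNS)].to_csv(path, index=False)
    return path


def read_feature_table(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a feature table, enforcing the schema; missing cells stay NaN."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_feature_schema(df.columns, str(path))
    return df


def _check_feature_schema(columns, context: str) -> None:
    got = list(columns)
    want = list(FEATURE_TABLE_COLUMNS)
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise ValueError(
            f"{context}: schema mismatch (missing {missing}, unexpected {extra}, order must match)"
        )


def write_reduced_table(reduced: pd.DataFrame, path: str | pathlib.Path) -> pathlib.Path:
    path = pathlib.Path(path)
    reduced.loc[:, list(REDUCED_COLUMNS)].to_csv(path, index=False)
    return path


def write_quality_report(reports: list[QualityReport], path: str | pathlib.Path) -> pathlib.Path:
    """Per-corpus inclusion report as structured text."""
    path = pathlib.Path(path)
    lines = ["# Quality gate report", ""]
    n_in = sum(r.included for r in reports)
    lines.append(f"records: {len(reports)}  included: {n_in}  excluded: {len(reports) - n_in}")
    lines.append("")
    for r in reports:
        lines.append(
            f"{r.record_id}: included={r.included} loss={r.signal_loss_fraction:.3f} "
            f"outliers={r.outlier_fraction:.3f} duration_min={r.duration_min:.1f}"
        )
        for reason in r.reasons:
            lines.append(f"  - {reason}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pca_report(
    results: dict[str, BlockPCAResult],
    path: str | pathlib.Path,
    bold_thresholds: dict[str, float] | None = None,
) -> pathlib.Path:
    """Feature-component correlation tables per block with the eigenvalue
    spectrum; correlations above the block's highlight threshold are
    marked with '*'."""
    thresholds = {"time": 0.99, "frequency": 0.80, "nonlinear": 0.77}
    if bold_thresholds:
        thresholds.update(bold_thresholds)
    path = pathlib.Path(path)
    lines = ["# Blockwise PCA report", ""]
    for name, res in results.items():
        thr = thresholds.get(name, 0.8)
        lines.append(f"## block: {name} (retained {res.retained_k})")
        lines.append(
            "eigenvalues: " + ", ".join(f"{v:.3f}" for _, v in eigenvalue_spectrum(res))
        )
        header = "feature".ljust(12) + "".join(
            f"{c:>12}" for c in res.correlations.columns
        )
        lines.append(header)
        for feat, row in res.correlations.iterrows():
            cells = "".join(
                f"{v:>11.3f}{'*' if abs(v) > thr else ' '}" for v in row
            )
            lines.append(feat.ljust(12) + cells)
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_model_report(
    ann_metrics,
    importance: pd.DataFrame,
    mlrm,
    path: str | pathlib.Path,
) -> pathlib.Path:
    """ANN metrics per subset, connection-weight importances, and the MLRM
    coefficient and diagnostic tables, as structured text."""
    path = pathlib.Path(path)
    lines = ["# Model report", "", "## ANN regression (counts vs reduced features)"]
    lines.append(f"{'subset':<10}{'R':>8}{'R2':>8}{'RMSE':>8}")
    for name, m in ann_metrics.per_subset.items():
        lines.append(f"{name:<10}{m['R']:>8.3f}{m['R2']:>8.3f}{m['RMSE']:>8.3f}")
    lines.append("")
    lines.append("## ANN connection-weight importance")
    for feat, row in importance.iterrows():
        lines.append(f"{feat:<16}{row['contribution']:>10.4f}{row['normalized']:>10.4f}")
    lines.append("")
    lines.append("## MLRM summary")
    lines.append(
        f"R={mlrm.r:.3f}  R2={mlrm.r2:.3f}  R2_adj={mlrm.r2_adjusted:.3f}  "
        f"error={mlrm.model_error:.3f}  DW={mlrm.durbin_watson:.3f}"
    )
    lines.append("")
    lines.append(f"{'variable':<16}{'coef':>10}{'std_coef':>10}{'p':>10}{'CI_lo':>10}{'CI_hi':>10}{'VIF':>8}")
    for var in mlrm.coefficients.index:
        std = mlrm.standardized_coefficients.get(var, float("nan"))
        vif = mlrm.vif.get(var, float("nan"))
        ci = mlrm.confidence_intervals.loc[var]
        lines.append(
            f"{var:<16}{mlrm.coefficients[var]:>10.3f}{std:>10.3f}"
            f"{mlrm.p_values[var]:>10.4f}{ci['lower']:>10.3f}{ci['upper']:>10.3f}{vif:>8.2f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_surfaces(surfaces, out_dir: str | pathlib.Path) -> list[pathlib.Path]:
    """One CSV grid per (week, FHR-mean) combination."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (wk, fm), grid in surfaces.surfaces.items():
        df = pd.DataFrame(
            grid,
            index=pd.Index(surfaces.grid_x, name=surfaces.vary[0]),
            columns=pd.Index(surfaces.grid_y, name=surfaces.vary[1]),
        )
        p = out_dir / f"surface_week{wk}_fhr{int(fm)}.csv"
        df.to_csv(p)
        paths.append(p)
    return paths
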