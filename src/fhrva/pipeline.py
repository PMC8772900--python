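"""End-to-end orchestration: generate -> preprocess -> featurize ->
reduce -> model -> surfaces.

A single YAML-serializable configuration drives every stage; one global
seed fans out to per-stage seeds through a counter-based derivation so
any stage can be rerun in isolation and the whole run is bitwise
reproducible.  Every intermediate table is written as plain text and the
run is summarized in a :class:`RunManifest`.
"""

from __future__ import annotations

import copy
import dataclasses
import datetime
import logging
import pathlib
import warnings

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .block_reduction import reduce_features
from .linear_features import FEATURE_NAMES, compute_linear_features
from .models import ann_importance, fit_mlrm, response_surface, split_data, train_ann
from .nonlinear_features import NonlinearParams, SymbolicConfig, compute_nonlinear_features
from .preprocessing import count_accelerations, preprocess_record
from .synthetic_ctg import ArtifactSpec, GeneratorConfig, generate_corpus

__all__ = ["DEFAULT_CONFIG", "PipelineError", "RunManifest", "load_config", "run_pipeline",
           "run_model_stage", "featurize_record", "stage_seed"]

logger = logging.getLogger("fhrva")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "fhrva-run",
    "n_records": 187,
    "stages": {
        "generate": True,
        "preprocess": True,
        "featurize": True,
        "reduce": True,
        "model": True,
        "surface": True,
    },
    "generator": {
        "sampling_rate": 4.0,
        "duration_s": 1800.0,
        "baseline_bpm": 140.0,
        "accel_rate": 8.5,
        "accel_amplitude_bpm": 15.0,
        "accel_duration_s": 20.0,
        "band_powers": {"vlf": 1.0, "lf": 6.0, "hf": 1.5},
        "drift_period_s": 600.0,
        "drift_amplitude_bpm": 4.0,
        "outlier_fraction": 0.005,
        "gap_count": 3,
        "gap_length_s": 2.0,
    },
    "preprocessing": {"max_gap_s": 3.0},
    "spectral": {"window_s": 30.0, "segment_s": 300.0},
    "nonlinear": {"m": 2, "r": 0.2, "k_max": 8, "n_levels": 6, "word_length": 3},
    "ann": {
        "hidden_grid": list(range(1, 11)),
        "n_restarts": 5,
        "max_epochs": 1000,
        "patience": 50,
        "learning_rate": 0.01,
    },
    "surface": {"grid_size": 25, "weeks": [30, 37, 41], "fhr_means": [110.0, 140.0, 170.0]},
}

_STAGE_ORDER = ("generate", "preprocess", "featurize", "reduce", "model", "surface")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and offending record."""

    def __init__(self, stage: str, cause: BaseException, record_id: str | None = None):
        self.stage = stage
        self.record_id = record_id
        where = f"stage '{stage}'" + (f", record '{record_id}'" if record_id else "")
        super().__init__(f"{where}: {cause}")


@dataclasses.dataclass
class RunManifest:
    config: dict
    counts: dict[str, int]
    stage_seeds: dict[str, int]
    version: str
    started: str
    finished: str
    notes: list[str] = dataclasses.field(default_factory=list)

    def to_yaml(self, path: str | pathlib.Path) -> pathlib.Path:
        path = pathlib.Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


def _validate_keys(cfg: dict, ref: dict, prefix: str = "") -> None:
    for key, value in cfg.items():
        if key not in ref:
            raise ValueError(f"unknown configuration key '{prefix}{key}'")
        if isinstance(ref[key], dict) and key not in ("band_powers",):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key '{prefix}{key}' must be a mapping")
            _validate_keys(value, ref[key], prefix=f"{prefix}{key}.")


def load_config(path: str | pathlib.Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional YAML file and explicit overrides;
    unknown keys are rejected."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for layer in (yaml.safe_load(pathlib.Path(path).read_text()) if path else None, overrides):
        if not layer:
            continue
        _validate_keys(layer, DEFAULT_CONFIG)
        for key, value in layer.items():
            if isinstance(value, dict) and key != "band_powers":
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stable across runs)."""
    idx = _STAGE_ORDER.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % 2**31)


def featurize_record(sig, record, config: dict) -> dict:
    """The 19 features of one preprocessed record."""
    spectral = config["spectral"]
    nl = config["nonlinear"]
    features: dict = {"record_id": record.record_id, "week": record.week}
    features.update(
        compute_linear_features(sig, window_s=spectral["window_s"], segment_s=spectral["segment_s"])
    )
    features.update(
        compute_nonlinear_features(
            sig,
            params=NonlinearParams(m=nl["m"], r=nl["r"], k_max=nl["k_max"]),
            sym_config=SymbolicConfig(n_levels=nl["n_levels"], word_length=nl["word_length"]),
        )
    )
    if record.accel_count_target is not None:
        features["accel_count"] = record.accel_count_target
    else:
        features["accel_count"] = count_accelerations(
            sig.fhr_clean, sig.floatingline, sig.sampling_rate
        )
    return features


def run_model_stage(
    reduced: pd.DataFrame,
    y: np.ndarray,
    config: dict,
    seed: int,
    out_dir: pathlib.Path | str,
) -> dict | None:
    """Fit ANN and MLRM on the reduced table and write the model report.

    A zero-variance target cannot be modeled: the stage warns and returns
    None without fitting.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        warnings.warn("zero-variance acceleration target; model stage skipped", stacklevel=2)
        return None
    try:
        split = split_data(len(reduced), seed)
        ann_cfg = config["ann"]
        model, metrics = train_ann(
            reduced,
            y,
            split,
            hidden_grid=tuple(ann_cfg["hidden_grid"]),
            n_restarts=ann_cfg["n_restarts"],
            max_epochs=ann_cfg["max_epochs"],
            patience=ann_cfg["patience"],
            learning_rate=ann_cfg["learning_rate"],
            seed=seed,
        )
        importance = ann_importance(model)
        mlrm = fit_mlrm(reduced, y)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("model", exc) from exc
    fio.write_model_report(metrics, importance, mlrm, pathlib.Path(out_dir) / "model_report.txt")
    return {"model": model, "metrics": metrics, "importance": importance, "mlrm": mlrm}


def run_pipeline(config: dict) -> RunManifest:
    """Execute the configured stages in order, writing all artifacts under
    ``config['out_dir']``.  Reruns with identical config reproduce every
    numeric output bitwise."""
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    out_dir = pathlib.Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    counts: dict[str, int] = {}
    seeds = {s: stage_seed(config["seed"], s) for s in _STAGE_ORDER}
    notes: list[str] = []

    gen = config["generator"]
    base_cfg = GeneratorConfig(
        sampling_rate=gen["sampling_rate"],
        duration_s=gen["duration_s"],
        baseline_bpm=gen["baseline_bpm"],
        accel_rate=gen["accel_rate"],
        accel_amplitude_bpm=gen["accel_amplitude_bpm"],
        accel_duration_s=gen["accel_duration_s"],
        band_powers=dict(gen["band_powers"]),
        drift_period_s=gen["drift_period_s"],
        drift_amplitude_bpm=gen["drift_amplitude_bpm"],
        artifact_spec=ArtifactSpec(
            outlier_fraction=gen["outlier_fraction"],
            gap_count=gen["gap_count"],
            gap_length_s=gen["gap_length_s"],
        ),
    )

    records, truths, sigs = [], {}, {}
    if stages["generate"]:
        try:
            records, truth_list, metadata = generate_corpus(
                config["n_records"], seeds["generate"], base_cfg
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("generate", exc) from exc
        truths = {r.record_id: t for r, t in zip(records, truth_list)}
        rec_dir = out_dir / "records"
        rec_dir.mkdir(exist_ok=True)
        for rec in records:
            fio.write_record(rec, rec_dir / f"{rec.record_id}.csv")
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        fio.write_ground_truth(truths, out_dir / "ground_truth.yaml")
        counts["generated"] = len(records)
        logger.info("generated %d records", len(records))

    reports = []
    if stages["preprocess"]:
        for rec in records:
            try:
                sig, report = preprocess_record(rec, max_gap_s=config["preprocessing"]["max_gap_s"])
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("preprocess", exc, rec.record_id) from exc
            reports.append(report)
            if sig is not None:
                sigs[rec.record_id] = sig
            logger.debug("preprocess %s included=%s", rec.record_id, report.included)
        fio.write_quality_report(reports, out_dir / "quality_report.txt")
        counts["gated_in"] = len(sigs)
        logger.info("gate passed by %d / %d records", len(sigs), len(records))

    feature_table = None
    if stages["featurize"]:
        rows = []
        for rec in records:
            if rec.record_id not in sigs:
                continue
            try:
                rows.append(featurize_record(sigs[rec.record_id], rec, config))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("featurize", exc, rec.record_id) from exc
            logger.debug("featurized %s", rec.record_id)
        feature_table = pd.DataFrame(rows, columns=["record_id", *FEATURE_NAMES, "accel_count"])
        fio.write_feature_table(feature_table, out_dir / "features.csv")
        counts["featurized"] = len(feature_table)

    reduced = None
    if stages["reduce"] and feature_table is not None:
        try:
            reduced, pca_results = reduce_features(feature_table)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("reduce", exc) from exc
        fio.write_reduced_table(reduced, out_dir / "reduced.csv")
        fio.write_pca_report(pca_results, out_dir / "pca_report.txt")
        counts["reduced_columns"] = reduced.shape[1]

    model = None
    if stages["model"] and reduced is not None:
        y = feature_table["accel_count"].to_numpy()
        fitted = run_model_stage(reduced, y, config, seeds["model"], out_dir)
        if fitted is None:
            notes.append("model stage skipped: zero-variance target")
        else:
            model = fitted["model"]
            counts["modeled"] = len(reduced)

    if stages["surface"] and model is not None:
        surf_cfg = config["surface"]
        try:
            surfaces = response_surface(
                model,
                reduced,
                weeks=tuple(surf_cfg["weeks"]),
                fhr_means=tuple(surf_cfg["fhr_means"]),
                grid_size=surf_cfg["grid_size"],
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("surface", exc) from exc
        fio.write_surfaces(surfaces, out_dir / "surfaces")
        counts["surfaces"] = len(surfaces.surfaces)

    finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest = RunManifest(
        config=copy.deepcopy(config),
        counts=counts,
        stage_seeds=seeds,
        version=_package_version(),
        started=started,
        finished=finished,
        notes=notes,
    )
    manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("fhrva")
    except PackageNotFoundError:
        return "unknown"
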