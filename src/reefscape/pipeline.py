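"""Config-driven orchestration of the full workflow with caching and a manifest.

Stages: source DEMs (loaded or synthesised) -> pyramid -> variable stack ->
vertical accuracy -> occurrence prep -> FC x RM tuning -> final model,
jackknife and prediction maps.  Each stage's inputs are content-hashed; a
stage is skipped when its hash matches the previous manifest and its
artifacts still exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accuracy import assess_stack, correct_to_lat, read_tides_csv, write_tides_csv
from .evaluation import jackknife, loro_cv, summarize_cv
from .grid import (Grid, build_dem_set, crop_to_reefs, read_raster,
                   read_reefs_geojson, write_raster, write_reefs_geojson)
from .maxent import FEATURE_CLASSES, FeatureSpec, fit_maxent
from .occurrence import build_feature_table, sample_background, thin_occurrences
from .synth import ReefSpec, ResponseSpec, generate_reef_dem, simulate_occurrences
from .terrain import TerrainParams, VariableStack, derive_all, layer_name

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; defaults mirror the canonical protocol."""

    out_dir: str = "run_out"
    # input paths; left None to synthesise fixtures instead
    aca_path: Optional[str] = None
    dr30_path: Optional[str] = None
    dr100_path: Optional[str] = None
    reefs_path: Optional[str] = None
    records_path: Optional[str] = None
    tides_path: Optional[str] = None
    synthetic: dict = field(default_factory=dict)  # ReefSpec / ResponseSpec overrides
    terrain: dict = field(default_factory=dict)  # TerrainParams overrides
    buffer_m: float = 500.0
    background_n: int = 10000
    background_bandwidth_m: float = 500.0
    background_epsilon: float = 0.05
    fc_grid: Tuple[str, ...] = ("L", "LQ", "LP", "LQP")
    rm_grid: Tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    n_iterations: int = 10
    n_replicates: int = 3
    seed: int = 0
    species: Tuple[str, ...] = ("SP1",)
    model_keys: Optional[List[str]] = None  # predictor layer names; None = all

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def validate_config(config: RunConfig) -> List[str]:
    """Static checks; returns a list of issue strings (empty = valid)."""
    issues = []
    if not config.fc_grid or not config.rm_grid:
        issues.append("error: fc/rm grid must be non-empty")
    for fc in config.fc_grid:
        if fc not in FEATURE_CLASSES:
            issues.append(f"error: unknown feature class {fc!r}")
    for rm in config.rm_grid:
        if rm <= 0:
            issues.append(f"error: rm must be > 0, got {rm}")
    if config.n_iterations < 1:
        issues.append("error: n_iterations must be >= 1")
    if config.buffer_m < 0:
        issues.append("error: buffer_m must be >= 0")
    if config.background_n < 1:
        issues.append("error: background_n must be >= 1")
    try:
        TerrainParams(**config.terrain)
    except (TypeError, ValueError) as exc:
        issues.append(f"error: terrain params: {exc}")
    for name in ("aca_path", "dr30_path", "dr100_path", "reefs_path",
                 "records_path", "tides_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            issues.append(f"error: {name} does not exist: {p}")
    paths = [config.aca_path, config.dr30_path, config.dr100_path]
    if any(paths) and not all(paths):
        issues.append("error: provide all three source DEM paths or none (synthetic)")
    if config.background_n < 10 * config.n_iterations:
        issues.append("warning: very few background points per iteration")
    return issues


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.doc = {"version": __version__, "stages": {}, "artifacts": {}}
        if path.exists():
            try:
                self.prev = json.loads(path.read_text())
            except json.JSONDecodeError:
                self.prev = {"stages": {}, "artifacts": {}}
        else:
            self.prev = {"stages": {}, "artifacts": {}}

    def cached(self, stage: str, input_hash: str) -> bool:
        prev = self.prev.get("stages", {}).get(stage)
        if not prev or prev.get("input_hash") != input_hash:
            return False
        arts = self.prev.get("artifacts", {}).get(stage, [])
        return bool(arts) and all(Path(a).exists() for a in arts)

    def record(self, stage: str, input_hash: str, artifacts: List[Path],
               elapsed: float, cached: bool) -> None:
        self.doc["stages"][stage] = {
            "input_hash": input_hash, "elapsed_s": round(elapsed, 3),
            "cached": cached, "timestamp": time.time(),
        }
        self.doc["artifacts"][stage] = [str(a) for a in artifacts]

    def write(self) -> None:
        self.path.write_text(json.dumps(self.doc, indent=2))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict."""
    issues = [i for i in validate_config(config) if i.startswith("error")]
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.doc["config"] = asdict(config)
    params = TerrainParams(**config.terrain)
    base_seed = config.seed

    # ---- stage: source DEMs -------------------------------------------------
    t0 = time.time()
    stage_hash = _hash_obj(["sources", config.synthetic, base_seed,
                            config.aca_path, config.dr30_path, config.dr100_path])
    synthetic = config.aca_path is None
    if synthetic:
        synth_cfg = dict(config.synthetic)
        resp_keys = {f for f in ResponseSpec.__dataclass_fields__}
        resp_cfg = {k: synth_cfg.pop(k) for k in list(synth_cfg) if k in resp_keys}
        spec = ReefSpec(seed=base_seed, **synth_cfg)
        aca15, dr30, dr100, reefs, truth = generate_reef_dem(spec)
        resp_cfg.setdefault("coefficients", {
            layer_name(("ACA", 15, "SLOPE")): 4.0,
            layer_name(("ACA", 15, "BPI")): 3.0,
        })
        resp = ResponseSpec(**resp_cfg)
    else:
        aca15 = read_raster(config.aca_path)
        dr30 = read_raster(config.dr30_path)
        dr100 = read_raster(config.dr100_path)
        reefs = read_reefs_geojson(config.reefs_path)
        truth = None
        resp = None
    src_cached = manifest.cached("sources", stage_hash)
    src_paths = [out / "ACA_15m_DEM.tif", out / "DR30_30m_DEM.tif",
                 out / "DR100_100m_DEM.tif", out / "reefs.geojson"]
    if not src_cached:
        for grid, p in zip((aca15, dr30, dr100), src_paths):
            write_raster(grid, p)
        write_reefs_geojson(reefs, src_paths[3])
    manifest.record("sources", stage_hash, src_paths, time.time() - t0, cached=src_cached)

    # ---- stage: pyramid -----------------------------------------------------
    t0 = time.time()
    stack = build_dem_set(aca15, dr30, dr100)
    pyr_hash = _hash_obj(["pyramid", stage_hash])
    pyr_cached = manifest.cached("pyramid", pyr_hash)
    dem_paths = []
    for (src, res), grid in stack.items():
        p = out / f"{src}_{res}m_DEM.tif"
        if not pyr_cached:
            write_raster(grid, p, dtype="float32")
        dem_paths.append(p)
    manifest.record("pyramid", pyr_hash, dem_paths, time.time() - t0, cached=pyr_cached)

    # ---- stage: variables ---------------------------------------------------
    t0 = time.time()
    var_hash = _hash_obj(["variables", stage_hash, asdict(params)])
    layer_dir = out / "layers"
    layer_dir.mkdir(exist_ok=True)
    if manifest.cached("variables", var_hash):
        variables = VariableStack()
        layer_paths = [Path(p) for p in manifest.prev["artifacts"]["variables"]]
        for p in layer_paths:
            key = tuple(p.stem.split("_", 2))
            variables.layers[(key[0], int(key[1].rstrip("m")), key[2])] = read_raster(p)
        manifest.record("variables", var_hash, layer_paths, time.time() - t0, cached=True)
    else:
        variables = derive_all(stack, params)
        layer_paths = []
        for key, grid in variables.items():
            p = layer_dir / f"{layer_name(key)}.tif"
            write_raster(grid, p, dtype="float32")
            layer_paths.append(p)
        manifest.record("variables", var_hash, layer_paths, time.time() - t0, cached=False)
    manifest.doc["n_variable_layers"] = len(variables)

    # ---- stage: occurrences / accuracy -------------------------------------
    t0 = time.time()
    if synthetic:
        presences_raw, all_coords, depth_records, tides = simulate_occurrences(
            variables, resp, reefs, seed=base_seed + 1, truth=truth)
    else:
        depth_records = pd.read_csv(config.records_path)
        presences_raw = depth_records[["record_id", "species_code", "x", "y", "reef_id"]]
        all_coords = presences_raw[["x", "y"]].to_numpy(dtype=float)
        tides = read_tides_csv(config.tides_path)
    stations = {rid: reefs.station_of(rid) for rid in reefs.reef_ids}
    corrected, _excluded = correct_to_lat(depth_records, tides, stations)
    accuracy_df = assess_stack(corrected, stack)
    acc_path = out / "vertical_accuracy.csv"
    accuracy_df.to_csv(acc_path, index=False)
    rec_path = out / "depth_records.csv"
    depth_records.to_csv(rec_path, index=False)
    tide_path = out / "tides.csv"
    write_tides_csv(tides, tide_path)
    manifest.record("accuracy", _hash_obj(["accuracy", stage_hash]),
                    [acc_path, rec_path, tide_path], time.time() - t0, cached=False)

    # ---- stage: feature table ----------------------------------------------
    t0 = time.time()
    thinned = thin_occurrences(presences_raw, stack[("ACA", 15)])
    reef_grids = crop_to_reefs(stack[("ACA", 15)], reefs, buffer_m=config.buffer_m)
    background = sample_background(all_coords, reef_grids, n=config.background_n,
                                  bias_bandwidth_m=config.background_bandwidth_m,
                                  seed=base_seed + 2, epsilon=config.background_epsilon)
    keys = config.model_keys or sorted(variables.names())
    table = build_feature_table(thinned, background, variables, keys)
    table_path = out / "feature_table.csv"
    table.to_csv(table_path, index=False)
    manifest.record("features", _hash_obj(["features", stage_hash, keys]),
                    [table_path], time.time() - t0, cached=False)

    # ---- stage: tuning ------------------------------------------------------
    t0 = time.time()
    from .maxent import select_parameters
    tune_hash = _hash_obj(["tuning", stage_hash, config.fc_grid, config.rm_grid,
                           config.n_iterations, config.n_replicates, keys])
    cv_path = out / "cv_records.csv"
    sel_path = out / "selection_table.csv"
    if manifest.cached("tuning", tune_hash):
        selection = pd.read_csv(sel_path)
        manifest.record("tuning", tune_hash, [cv_path, sel_path],
                        time.time() - t0, cached=True)
    else:
        cv_records = []
        for fc in config.fc_grid:
            for rm in config.rm_grid:
                spec_fr = FeatureSpec(fc=fc, base_columns=keys)
                rec = loro_cv(table, spec_fr, rm, n_iterations=config.n_iterations,
                              seed=base_seed + 3, n_replicates=config.n_replicates)
                cv_records.append(rec)
        cv_df = pd.concat(cv_records, ignore_index=True)
        selection = select_parameters(summarize_cv(cv_df))
        cv_df.to_csv(cv_path, index=False)
        selection.to_csv(sel_path, index=False)
        manifest.record("tuning", tune_hash, [cv_path, sel_path],
                        time.time() - t0, cached=False)

    # ---- stage: final model -------------------------------------------------
    t0 = time.time()
    win = selection[selection["winner"]].iloc[0]
    final_spec = FeatureSpec(fc=str(win["fc"]), base_columns=keys)
    model = fit_maxent(table, final_spec, float(win["rm"]), seed=base_seed)
    model_path = out / "final_model.json"
    model_path.write_text(model.to_json())
    jk = jackknife(table, final_spec, float(win["rm"]), seed=base_seed + 4)
    jk_path = out / "jackknife.csv"
    jk.to_csv(jk_path, index=False)
    pred = model.predict_raster(variables)
    pred_path = out / "prediction_ACA_15m.tif"
    write_raster(pred, pred_path, dtype="float32")
    manifest.record("final", _hash_obj(["final", stage_hash, str(win["fc"]),
                                        float(win["rm"])]),
                    [model_path, jk_path, pred_path], time.time() - t0, cached=False)

    manifest.doc["summary"] = {
        "winner_fc": str(win["fc"]), "winner_rm": float(win["rm"]),
        "mean_auc_test": float(win["mean_auc_test"]),
        "n_variable_layers": len(variables),
        "n_selection_rows": len(selection),
    }
    manifest.write()
    return manifest.doc
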