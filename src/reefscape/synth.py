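"""Seeded synthetic reef fixtures: co-registered multi-resolution DEMs, tide
tables, colony depth records and occurrences with a known terrain response.

The truth bathymetry is an analytic function of position — a radial
lagoon/flat/crest/slope profile per reef plus a continuous random roughness
field built from random cosine modes — so it can be sampled consistently at
any resolution.  The three "source" DEMs are the truth sampled at 15/30/100 m
cell centres with independent sensor noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .accuracy import TideTable
from .grid import Grid, RasterError, ReefSet
from .terrain import VariableStack, layer_name

logger = logging.getLogger(__name__)

CRS_ID = "SYNTH:1"
_TIDE_PERIOD_S = 12.42 * 3600.0  # semidiurnal


@dataclass
class ReefSpec:
    """Geometry and noise parameters of the synthetic reef landscape."""

    n_reefs: int = 3
    reef_radius_m: float = 600.0
    lagoon_depth_m: float = 6.0
    crest_depth_m: float = 1.0
    slope_max_depth_m: float = 30.0
    noise_sd_m: float = 0.3
    roughness_corr_length_m: float = 120.0
    roughness_sd_m: float = 0.5
    seed: int = 0
    fine_res_m: float = 15.0
    n_roughness_modes: int = 96

    def __post_init__(self) -> None:
        if not (self.crest_depth_m < self.lagoon_depth_m < self.slope_max_depth_m):
            raise ValueError("require crest_depth < lagoon_depth < slope_max_depth")
        if self.noise_sd_m < 0 or self.roughness_sd_m < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_reefs < 1:
            raise ValueError("n_reefs must be >= 1")


@dataclass
class ResponseSpec:
    """Known logistic terrain response used to place occurrences."""

    coefficients: Dict[str, float]  # variable layer name -> beta (scaled variables)
    intercept: float = 0.0
    n_presence: int = 200
    depth_cap_m: float = 8.0
    gps_noise_sd_m: float = 3.0
    depth_noise_sd_m: float = 1.0
    tide_amplitude_m: float = 1.5
    species_code: str = "SP1"

    def __post_init__(self) -> None:
        if self.depth_cap_m <= 0:
            raise ValueError("depth_cap_m must be > 0")
        if min(self.gps_noise_sd_m, self.depth_noise_sd_m) < 0:
            raise ValueError("noise SDs must be >= 0")


class TruthSurface:
    """Analytic truth bathymetry evaluable at arbitrary coordinates."""

    def __init__(self, spec: ReefSpec, centers: np.ndarray, rng: np.random.Generator):
        self.spec = spec
        self.centers = centers
        R = spec.reef_radius_m
        # radial profile knots (fractions of the reef radius -> depth in m)
        self._knots_r = np.array([0.0, 0.35, 0.55, 0.70, 1.50, 1e9]) * R
        self._knots_z = -np.array([
            spec.lagoon_depth_m, spec.lagoon_depth_m, spec.crest_depth_m,
            spec.crest_depth_m, spec.slope_max_depth_m, spec.slope_max_depth_m])
        # random cosine modes with Gaussian-decay spectrum: a continuous,
        # seed-deterministic roughness field with the requested scale
        m = spec.n_roughness_modes
        ell = max(spec.roughness_corr_length_m, 1e-6)
        self._wave = rng.normal(scale=1.0 / ell, size=(m, 2))
        self._phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
        self._amp = spec.roughness_sd_m * math.sqrt(2.0 / m)

    def radial(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Profile part alone (no roughness); shallowest reef wins."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.full(np.broadcast(x, y).shape, -self.spec.slope_max_depth_m)
        for cx, cy in self.centers:
            r = np.hypot(x - cx, y - cy)
            z = np.maximum(z, np.interp(r, self._knots_r, self._knots_z))
        return z

    def roughness(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        phase = x * self._wave[:, 0] + y * self._wave[:, 1] + self._phase
        return self._amp * np.cos(phase).sum(axis=-1)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.radial(x, y) + self.roughness(x, y)


def _layout(spec: ReefSpec) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Reef centres in a row and the fine-grid shape that contains them."""
    R = spec.reef_radius_m
    spacing = 3.2 * R
    width = spec.n_reefs * spacing + 0.4 * R
    height = 3.6 * R
    px = spec.fine_res_m
    # snap the domain to multiples of 8 fine pixels so 15/30/60/120 m grids nest
    ncols = int(math.ceil(width / px / 8.0)) * 8
    nrows = int(math.ceil(height / px / 8.0)) * 8
    if ncols * px < 2 * R or nrows * px < 2 * R:
        raise RasterError("grid too small for the requested reef radius")
    cx = (np.arange(spec.n_reefs) + 0.5) * spacing + 0.2 * R
    cy = np.full(spec.n_reefs, nrows * px / 2.0)
    return np.column_stack([cx, cy]), (nrows, ncols)


def _sample_grid(truth: TruthSurface, res: float, shape_fine: Tuple[int, int],
                 fine_res: float, noise_sd: float, rng: np.random.Generator,
                 source_tag: str) -> Grid:
    nrows = int(round(shape_fine[0] * fine_res / res))
    ncols = int(round(shape_fine[1] * fine_res / res))
    y0 = shape_fine[0] * fine_res
    xs = (np.arange(ncols) + 0.5) * res
    ys = y0 - (np.arange(nrows) + 0.5) * res
    gx, gy = np.meshgrid(xs, ys)
    vals = truth(gx, gy)
    if noise_sd > 0:
        vals = vals + rng.normal(scale=noise_sd, size=vals.shape)
    return Grid(values=vals, transform=(0.0, y0, res), crs_id=CRS_ID,
                nodata_mask=np.zeros(vals.shape, dtype=bool), source_tag=source_tag)


def generate_reef_dem(spec: ReefSpec) -> Tuple[Grid, Grid, Grid, ReefSet, TruthSurface]:
    """Three co-located source DEMs (15/30/100 m), reef outlines and the truth.

    Deterministic per ``spec.seed``; sensor noise is independent between
    sources.
    """
    rng = np.random.default_rng(spec.seed)
    centers, shape_fine = _layout(spec)
    truth = TruthSurface(spec, centers, rng)
    noise_rngs = rng.spawn(3)
    aca15 = _sample_grid(truth, spec.fine_res_m, shape_fine, spec.fine_res_m,
                         spec.noise_sd_m, noise_rngs[0], "ACA")
    dr30 = _sample_grid(truth, 30.0, shape_fine, spec.fine_res_m,
                        spec.noise_sd_m, noise_rngs[1], "DR30")
    dr100 = _sample_grid(truth, 100.0, shape_fine, spec.fine_res_m,
                         spec.noise_sd_m, noise_rngs[2], "DR100")
    reefs = ReefSet(reefs=[
        (f"reef{i}", Point(cx, cy).buffer(1.6 * spec.reef_radius_m), f"station{i}")
        for i, (cx, cy) in enumerate(centers)])
    return aca15, dr30, dr100, reefs, truth


def make_tides(reefs: ReefSet, amplitude_m: float, seed: int | None = None,
               n_days: float = 14.0, step_s: float = 3600.0) -> Dict[str, TideTable]:
    """One semidiurnal sinusoid per station, heights in [0, amplitude]."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, n_days * 86400.0 + step_s, step_s)
    tides = {}
    for _, _, station in reefs:
        if station in tides:
            continue
        phase = rng.uniform(0.0, 2.0 * np.pi)
        heights = 0.5 * amplitude_m * (1.0 + np.sin(2.0 * np.pi * times / _TIDE_PERIOD_S + phase))
        tides[station] = TideTable(station_id=station, times=times, heights=heights)
    return tides


def simulate_occurrences(stack: VariableStack, resp: ResponseSpec, reefs: ReefSet,
                         seed: int | None = None, truth: TruthSurface | None = None,
                         ) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame,
                                    Dict[str, TideTable]]:
    """Presences from a known logistic response, plus depth records and tides.

    Candidate cells are valid cells of the finest DEPTH layer with depth
    within ``depth_cap_m`` that fall inside a reef polygon.  The presence
    probability is logistic(intercept + sum beta * z-scored variable);
    ``n_presence`` cells are drawn without replacement with that weight.
    Coordinates get GPS jitter; depth records carry truth depth plus tide at
    the observation time plus dive-computer noise.

    Returns (presences, all_coords, depth_records, tides).
    """
    import shapely

    rng = np.random.default_rng(seed)
    depth_keys = [k for k in stack.keys() if k[2] == "DEPTH"]
    if not depth_keys:
        raise ValueError("stack lacks a DEPTH layer")
    ref_key = min(depth_keys, key=lambda k: k[1])
    ref = stack[ref_key]

    for name in resp.coefficients:
        if name not in stack.names():
            raise KeyError(f"response variable {name!r} not in stack")

    gx, gy = ref.cell_centers()
    depth = ref.values
    candidate = ref.valid_mask & (depth >= -resp.depth_cap_m) & (depth < 0)
    # restrict to reef polygons and record the reef id per cell
    reef_of = np.full(ref.shape, -1, dtype=int)
    for i, (rid, poly, _) in enumerate(reefs):
        inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel()).reshape(ref.shape)
        reef_of[inside & (reef_of < 0)] = i
    candidate &= reef_of >= 0
    idx = np.flatnonzero(candidate.ravel())
    if idx.size == 0:
        raise RasterError("no candidate cells within the depth cap")
    if idx.size < resp.n_presence:
        raise RasterError(f"only {idx.size} candidate cells for "
                          f"{resp.n_presence} presences")

    eta = np.full(idx.size, float(resp.intercept))
    for name, beta in resp.coefficients.items():
        layer = stack.by_name(name)
        if layer.shape != ref.shape:
            raise ValueError(f"layer {name} not co-registered with reference DEPTH")
        v = layer.values.ravel()[idx]
        v = np.where(np.isfinite(v), v, np.nanmedian(v))
        sd = v.std()
        scaled = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        eta += beta * scaled
    prob = 1.0 / (1.0 + np.exp(-eta))
    pick = rng.choice(idx.size, size=resp.n_presence, replace=False,
                      p=prob / prob.sum())
    chosen = idx[pick]
    rows, cols = np.unravel_index(chosen, ref.shape)
    true_x = gx[rows, cols]
    true_y = gy[rows, cols]
    reef_ids = np.array(reefs.reef_ids)[reef_of[rows, cols]]

    tides = make_tides(reefs, resp.tide_amplitude_m, seed=seed)
    spans = {s: (t.times[0], t.times[-1]) for s, t in tides.items()}
    timestamps = np.empty(resp.n_presence)
    for i, rid in enumerate(reef_ids):
        lo, hi = spans[reefs.station_of(rid)]
        timestamps[i] = rng.uniform(lo + 1.0, hi - 1.0)

    obs_x = true_x + rng.normal(scale=resp.gps_noise_sd_m, size=resp.n_presence)
    obs_y = true_y + rng.normal(scale=resp.gps_noise_sd_m, size=resp.n_presence)
    if truth is not None:
        true_depth = -truth(true_x, true_y)
    else:
        true_depth = -ref.values[rows, cols]
    tide_h = np.array([tides[reefs.station_of(r)].height_at(t)
                       for r, t in zip(reef_ids, timestamps)])
    raw_depth = np.maximum(
        true_depth - tide_h + rng.normal(scale=resp.depth_noise_sd_m,
                                         size=resp.n_presence), 0.0)

    presences = pd.DataFrame({
        "record_id": np.arange(resp.n_presence),
        "species_code": resp.species_code,
        "x": obs_x, "y": obs_y, "reef_id": reef_ids,
    })
    depth_records = presences.assign(raw_depth=raw_depth, timestamp=timestamps)
    all_coords = np.column_stack([obs_x, obs_y])
    return presences, all_coords, depth_records, tides
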