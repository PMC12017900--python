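"""Topographic variable derivation from bathymetric DEMs.

Nine predictor layers per DEM level: depth itself plus slope, the two aspect
components (eastness/northness), vertical and horizontal curvature, vector
ruggedness, position index against an annulus neighbourhood, and sky view
factor.  Slope, aspect and curvature share a local quadratic surface fit
(Evans-style): z = a x^2 + b y^2 + c xy + d x + e y + f over a small window,
with x east and y north in metres.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import Grid, MultiscaleStack, RasterError

logger = logging.getLogger(__name__)

VARIABLE_CODES = ("DEPTH", "SLOPE", "EAST", "NORTH", "VCU", "HCU", "VRM", "BPI", "SVF")

#: slope below which a cell is treated as flat (aspect undefined)
FLAT_SLOPE_TOL = 1e-6

LayerKey = Tuple[str, int, str]  # (source_tag, resolution_m, variable_code)


def layer_name(key: LayerKey) -> str:
    src, res, var = key
    return f"{src}_{res}m_{var}"


def parse_layer_name(name: str) -> LayerKey:
    src, res, var = name.split("_", 2)
    return src, int(res.rstrip("m")), var


@dataclass
class TerrainParams:
    """Window and radius parameters for the terrain operators (cell units)."""

    fit_window: int = 3
    vrm_window: int = 3
    bpi_inner_r: float = 1.0
    bpi_outer_r: float = 3.0
    svf_azimuths: int = 16
    svf_radius: int = 10

    def __post_init__(self) -> None:
        for name in ("fit_window", "vrm_window"):
            w = getattr(self, name)
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        if not (self.bpi_outer_r > self.bpi_inner_r >= 0):
            raise ValueError("require bpi_outer_r > bpi_inner_r >= 0")
        if self.svf_azimuths < 4:
            raise ValueError("svf_azimuths must be >= 4")
        if self.svf_radius < 1:
            raise ValueError("svf_radius must be >= 1")


@dataclass
class VariableStack:
    """Keyed collection of derived layers: (source, resolution, variable) -> Grid."""

    layers: Dict[LayerKey, Grid] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, key: LayerKey) -> Grid:
        return self.layers[key]

    def __contains__(self, key: LayerKey) -> bool:
        return key in self.layers

    def keys(self):
        return self.layers.keys()

    def items(self):
        return self.layers.items()

    def names(self):
        return [layer_name(k) for k in self.layers]

    def by_name(self, name: str) -> Grid:
        return self.layers[parse_layer_name(name)]


# ---------------------------------------------------------------------------
# Local quadratic surface fit
# ---------------------------------------------------------------------------

def _quadratic_kernels(window: int, px: float) -> np.ndarray:
    """Per-coefficient correlation kernels for the windowed least-squares fit.

    Returns an array of shape (6, window, window): one kernel per coefficient
    in the order (a, b, c, d, e, f) of z = a x^2 + b y^2 + c xy + d x + e y + f.
    """
    h = window // 2
    rows = []
    for dr in range(-h, h + 1):
        for dc in range(-h, h + 1):
            x = dc * px
            y = -dr * px  # row index grows southward
            rows.append([x * x, y * y, x * y, x, y, 1.0])
    design = np.array(rows)
    pinv = np.linalg.pinv(design)  # (6, window**2)
    return pinv.reshape(6, window, window)


def local_quadratic(dem: Grid, params: TerrainParams | None = None) -> Dict[str, np.ndarray]:
    """Fit the local quadratic surface and return derivative arrays.

    Output dict has keys ``zx, zy, zxx, zyy, zxy`` (per-metre units) plus
    ``valid``: cells whose full window contains no nodata (grid edges use
    reflect padding and stay valid).
    """
    params = params or TerrainParams()
    w = params.fit_window
    nr, nc = dem.shape
    if w > nr or w > nc:
        raise RasterError(f"fit window {w} larger than grid {dem.shape}")
    kernels = _quadratic_kernels(w, dem.pixel_size)
    vals = np.where(dem.valid_mask, dem.values, 0.0)
    coeffs = [ndimage.correlate(vals, k, mode="reflect") for k in kernels]
    a, b, c, d, e, _f = coeffs
    valid = ndimage.binary_erosion(dem.valid_mask, structure=np.ones((w, w)), border_value=1)
    return {"zx": d, "zy": e, "zxx": 2.0 * a, "zyy": 2.0 * b, "zxy": c, "valid": valid}


def slope(dem: Grid, params: TerrainParams | None = None) -> Grid:
    """Slope in radians: arctan of the gradient magnitude, in [0, pi/2)."""
    q = local_quadratic(dem, params)
    s = np.arctan(np.hypot(q["zx"], q["zy"]))
    s[~q["valid"]] = np.nan
    return dem.with_values(s, nodata_mask=~q["valid"])


def aspect_components(dem: Grid, params: TerrainParams | None = None) -> Tuple[Grid, Grid]:
    """Eastness and northness of the downslope azimuth (north 0, clockwise).

    Flat cells (slope < tolerance) are nodata in both components.
    """
    q = local_quadratic(dem, params)
    grad = np.hypot(q["zx"], q["zy"])
    az = np.arctan2(-q["zx"], -q["zy"])  # downslope direction
    defined = q["valid"] & (np.arctan(grad) >= FLAT_SLOPE_TOL)
    east = np.where(defined, np.sin(az), np.nan)
    north = np.where(defined, np.cos(az), np.nan)
    return (dem.with_values(east, nodata_mask=~defined),
            dem.with_values(north, nodata_mask=~defined))


def curvatures(dem: Grid, params: TerrainParams | None = None) -> Tuple[Grid, Grid]:
    """Profile (VCU) and plan (HCU) curvature, radians per metre.

    Signs: VCU > 0 where the surface is upwardly concave along the slope
    line; HCU > 0 where contours bulge outward (sideward convex).  Cells with
    near-zero gradient are 0 by convention.
    """
    q = local_quadratic(dem, params)
    zx, zy, zxx, zyy, zxy = q["zx"], q["zy"], q["zxx"], q["zyy"], q["zxy"]
    g2 = zx * zx + zy * zy
    flat = g2 < FLAT_SLOPE_TOL**2
    g2safe = np.where(flat, 1.0, g2)
    vcu = (zxx * zx * zx + 2.0 * zxy * zx * zy + zyy * zy * zy) / (
        g2safe * (1.0 + g2safe) ** 1.5)
    hcu = -(zxx * zy * zy - 2.0 * zxy * zx * zy + zyy * zx * zx) / g2safe**1.5
    vcu = np.where(flat, 0.0, vcu)
    hcu = np.where(flat, 0.0, hcu)
    bad = ~q["valid"]
    vcu[bad] = np.nan
    hcu[bad] = np.nan
    return dem.with_values(vcu, nodata_mask=bad), dem.with_values(hcu, nodata_mask=bad.copy())


def vrm(dem: Grid, params: TerrainParams | None = None) -> Grid:
    """Vector ruggedness: 1 minus the normalised resultant of unit normals.

    Per-cell unit normal (sin s sin a, sin s cos a, cos s) from slope s and
    aspect a; summed over the vrm_window and normalised by the number of
    valid contributing cells, so the result sits in [0, 1].
    """
    params = params or TerrainParams()
    q = local_quadratic(dem, params)
    s = np.arctan(np.hypot(q["zx"], q["zy"]))
    az = np.arctan2(-q["zx"], -q["zy"])
    valid = q["valid"]
    sin_s = np.where(valid, np.sin(s), 0.0)
    nx = sin_s * np.sin(az)
    ny = sin_s * np.cos(az)
    nz = np.where(valid, np.cos(s), 0.0)
    ones = np.ones((params.vrm_window, params.vrm_window))
    sx = ndimage.correlate(nx, ones, mode="reflect")
    sy = ndimage.correlate(ny, ones, mode="reflect")
    sz = ndimage.correlate(nz, ones, mode="reflect")
    cnt = ndimage.correlate(valid.astype(float), ones, mode="reflect")
    ok = valid & (cnt > 0)
    resultant = np.sqrt(sx * sx + sy * sy + sz * sz)
    out = np.full(dem.shape, np.nan)
    out[ok] = 1.0 - resultant[ok] / cnt[ok]
    out = np.clip(out, 0.0, 1.0, out=out, where=ok)
    return dem.with_values(out, nodata_mask=~ok)


def _annulus_footprint(inner_r: float, outer_r: float) -> np.ndarray:
    r = int(math.ceil(outer_r))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    dist = np.hypot(dr, dc)
    return ((dist > inner_r) & (dist <= outer_r)).astype(float)


def bpi(dem: Grid, params: TerrainParams | None = None) -> Grid:
    """Position index (m): cell elevation minus the mean over an annulus.

    Positive on local highs.  Cells with an empty valid annulus are nodata.
    """
    params = params or TerrainParams()
    fp = _annulus_footprint(params.bpi_inner_r, params.bpi_outer_r)
    valid = dem.valid_mask
    vals = np.where(valid, dem.values, 0.0)
    num = ndimage.correlate(vals, fp, mode="reflect")
    den = ndimage.correlate(valid.astype(float), fp, mode="reflect")
    ok = valid & (den > 0)
    out = np.full(dem.shape, np.nan)
    out[ok] = dem.values[ok] - num[ok] / den[ok]
    return dem.with_values(out, nodata_mask=~ok)


def svf(dem: Grid, params: TerrainParams | None = None) -> Grid:
    """Sky view factor via horizon angles along sampled azimuth rays.

    For each azimuth the horizon angle is the largest positive elevation
    angle to any ray sample within ``svf_radius`` cells (1-cell steps,
    nearest-cell sampling); SVF = 1 - mean(sin horizon) over azimuths, giving
    1 on flat terrain and approaching 0 in an enclosing pit.  Rays truncated
    by the grid edge use the available samples.
    """
    params = params or TerrainParams()
    nr, nc = dem.shape
    pad = params.svf_radius
    z = np.where(dem.valid_mask, dem.values, np.nan)
    zp = np.full((nr + 2 * pad, nc + 2 * pad), np.nan)
    zp[pad:pad + nr, pad:pad + nc] = z
    px = dem.pixel_size
    azimuths = 2.0 * np.pi * np.arange(params.svf_azimuths) / params.svf_azimuths
    sin_sum = np.zeros((nr, nc))
    for az in azimuths:
        max_tan = np.full((nr, nc), -np.inf)
        for t in range(1, params.svf_radius + 1):
            ddr = int(round(-math.cos(az) * t))  # north is -row
            ddc = int(round(math.sin(az) * t))
            if ddr == 0 and ddc == 0:
                continue
            dist = math.hypot(ddr, ddc) * px
            zs = zp[pad + ddr:pad + ddr + nr, pad + ddc:pad + ddc + nc]
            with np.errstate(invalid="ignore"):
                tan_a = (zs - z) / dist
            max_tan = np.fmax(max_tan, tan_a)
        h = np.arctan(np.clip(max_tan, 0.0, None))
        h[~np.isfinite(max_tan)] = 0.0
        sin_sum += np.sin(h)
    out = 1.0 - sin_sum / params.svf_azimuths
    out[dem.nodata_mask] = np.nan
    return dem.with_values(np.clip(out, 0.0, 1.0), nodata_mask=dem.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Stack assembly and cross-source comparison
# ---------------------------------------------------------------------------

def derive_all(stack: MultiscaleStack, params: TerrainParams | None = None) -> VariableStack:
    """Derive depth plus the eight attributes for every DEM level.

    Layer count is 9 x |stack| (72 for the canonical eight-DEM set).
    """
    params = params or TerrainParams()
    out = VariableStack()
    for (src, res), dem in stack.items():
        try:
            out.layers[(src, res, "DEPTH")] = dem.copy()
            out.layers[(src, res, "SLOPE")] = slope(dem, params)
            east, north = aspect_components(dem, params)
            out.layers[(src, res, "EAST")] = east
            out.layers[(src, res, "NORTH")] = north
            vcu, hcu = curvatures(dem, params)
            out.layers[(src, res, "VCU")] = vcu
            out.layers[(src, res, "HCU")] = hcu
            out.layers[(src, res, "VRM")] = vrm(dem, params)
            out.layers[(src, res, "BPI")] = bpi(dem, params)
            out.layers[(src, res, "SVF")] = svf(dem, params)
        except Exception as exc:  # annotate the offending layer
            raise RasterError(f"failed deriving ({src}, {res} m): {exc}") from exc
    assert len(out) == 9 * len(stack)
    return out


def compare_sources(a: VariableStack, b: VariableStack, n_points: int = 15000,
                    seed: int | None = None, threshold: float = 0.8) -> pd.DataFrame:
    """Spearman correlation between two stacks at shared (resolution, variable) keys.

    Values are sampled at up to ``n_points`` seeded random cells valid in both
    layers (at most one point per cell).  Pairs with fewer than 3 shared valid
    points get NaN.  Returns a report with columns variable_code,
    resolution_m, r_s, n_points, flagged (|r_s| >= threshold).
    """
    rng = np.random.default_rng(seed)
    keys_a = {(res, var): (src, res, var) for (src, res, var) in a.keys()}
    keys_b = {(res, var): (src, res, var) for (src, res, var) in b.keys()}
    shared = sorted(set(keys_a) & set(keys_b))
    if not shared:
        raise RasterError("no shared (resolution, variable) keys between stacks")
    rows = []
    for res, var in shared:
        ga, gb = a[keys_a[(res, var)]], b[keys_b[(res, var)]]
        if ga.shape != gb.shape:
            raise RasterError(f"shape mismatch for ({res}, {var})")
        both = ga.valid_mask & gb.valid_mask
        idx = np.flatnonzero(both.ravel())
        if idx.size > n_points:
            idx = rng.choice(idx, size=n_points, replace=False)
        va = ga.values.ravel()[idx]
        vb = gb.values.ravel()[idx]
        if idx.size < 3:
            rs = np.nan
        else:
            rs = float(stats.spearmanr(va, vb).statistic)
        rows.append({"variable_code": var, "resolution_m": res, "r_s": rs,
                     "n_points": int(idx.size),
                     "flagged": bool(abs(rs) >= threshold) if np.isfinite(rs) else False})
    return pd.DataFrame(rows)
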