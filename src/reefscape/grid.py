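"""Raster grids, GeoTIFF I/O, DEM preprocessing and Gaussian-pyramid generalisation.

A :class:`Grid` is a single-band raster with a minimal north-up affine
transform ``(x_origin, y_origin, pixel_size_m)``: pixel ``(r, c)`` covers the
half-open square ``[x0 + c*px, x0 + (c+1)*px) x (y0 - (r+1)*px, y0 - r*px]``.
Pixels are square and elevations are metres, negative below sea level.

GeoTIFF files are read and written through :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata tag, so the
files interoperate with GDAL-based stacks.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

SOURCE_TAGS = ("ACA", "DR30", "DR100", "SYNTH")

#: canonical nesting scheme: native resolution -> pyramid levels per source
NESTING_SCHEME: Dict[str, Tuple[int, ...]] = {
    "ACA": (15, 30, 60, 120),
    "DR30": (30, 60, 120),
    "DR100": (100,),
}

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: classic 5-tap binomial REDUCE kernel
PYRAMID_KERNEL_1D = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class RasterError(ValueError):
    """Raised for malformed rasters or incompatible grid operations."""


@dataclass
class Grid:
    """Single-band raster with square pixels and a top-left origin."""

    values: np.ndarray
    transform: Tuple[float, float, float]  # (x_origin, y_origin, pixel_size_m)
    crs_id: str
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_tag: str = "SYNTH"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError(f"grid values must be 2-D, got {self.values.ndim}-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise RasterError("nodata_mask shape mismatch")
        if self.pixel_size <= 0:
            raise RasterError(f"pixel size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise RasterError("non-finite values on valid cells")

    # -- geometry helpers ---------------------------------------------------
    @property
    def pixel_size(self) -> float:
        return float(self.transform[2])

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def x_origin(self) -> float:
        return float(self.transform[0])

    @property
    def y_origin(self) -> float:
        return float(self.transform[1])

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points ``(x, y)``."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.pixel_size).astype(int)
        row = np.floor((self.y_origin - y) / self.pixel_size).astype(int)
        return row, col

    def inside(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Arrays of x- and y-coordinates of every cell centre (2-D)."""
        nr, nc = self.shape
        xs = self.x_origin + (np.arange(nc) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(nr) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell values at points; NaN outside the grid or on nodata."""
        row, col = self.cell_of(x, y)
        ok = self.inside(row, col)
        out = np.full(row.shape, np.nan)
        r, c = row[ok], col[ok]
        vals = self.values[r, c].astype(float)
        vals[self.nodata_mask[r, c]] = np.nan
        out[ok] = vals
        return out

    def with_values(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Grid":
        return Grid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            crs_id=self.crs_id,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else nodata_mask,
            source_tag=self.source_tag,
        )

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy(), nodata_mask=self.nodata_mask.copy())


@dataclass
class MultiscaleStack:
    """Nested multi-resolution DEM collection keyed by (source_tag, resolution_m)."""

    levels: Dict[Tuple[str, int], Grid]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, key: Tuple[str, int]) -> Grid:
        return self.levels[key]

    def keys(self):
        return self.levels.keys()

    def items(self):
        return self.levels.items()

    def validate(self) -> None:
        crs = {g.crs_id for g in self.levels.values()}
        if len(crs) > 1:
            raise RasterError(f"stack mixes CRS ids: {sorted(crs)}")
        for (src, res), grid in self.levels.items():
            if not math.isclose(grid.pixel_size, res, rel_tol=1e-6):
                raise RasterError(f"level ({src},{res}) has pixel size {grid.pixel_size}")


@dataclass
class ReefSet:
    """Reef outline polygons with their assigned tide stations."""

    reefs: List[Tuple[str, BaseGeometry, str]]  # (reef_id, polygon, tide_station_id)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reefs]
        if len(ids) != len(set(ids)):
            raise RasterError("duplicate reef ids")
        for rid, poly, _ in self.reefs:
            if poly.is_empty:
                raise RasterError(f"reef {rid!r} has an empty polygon")

    def __iter__(self):
        return iter(self.reefs)

    def __len__(self) -> int:
        return len(self.reefs)

    @property
    def reef_ids(self) -> List[str]:
        return [r[0] for r in self.reefs]

    def station_of(self, reef_id: str) -> str:
        for rid, _, station in self.reefs:
            if rid == reef_id:
                return station
        raise KeyError(reef_id)

    def polygon_of(self, reef_id: str) -> BaseGeometry:
        for rid, poly, _ in self.reefs:
            if rid == reef_id:
                return poly
        raise KeyError(reef_id)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(grid: Grid, path: str | Path, dtype: str | None = None) -> Path:
    """Write a Grid as a single-band GeoTIFF with geo tags and nodata set.

    ``dtype=None`` keeps float64 (lossless round-trip); pass ``"float32"`` for
    compact interchange files.
    """
    path = Path(path)
    out = grid.values.astype(dtype or "float64").copy()
    out[grid.nodata_mask] = np.nan
    x0, y0, px = grid.transform
    meta = json.dumps({"crs_id": grid.crs_id, "source_tag": grid.source_tag})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, out, extratags=extratags, description=meta)
    return path


def read_raster(path: str | Path, band: int = 0) -> Grid:
    """Read a GeoTIFF into a Grid, masking nodata cells.

    Raises :class:`RasterError` for a missing file, non-square pixels or a
    missing geotransform.
    """
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = np.asarray(tif.asarray(), dtype=float)
        if arr.ndim == 3:
            arr = arr[band] if arr.shape[0] < arr.shape[-1] else arr[..., band]
        elif band not in (0, 1):
            raise RasterError(f"band {band} requested from single-band file {path}")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"missing geotransform tags in {path}")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise RasterError(f"non-square pixels ({sx} x {sy}) in {path}")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        x0 = tie[3] - tie[0] * sx
        y0 = tie[4] + tie[1] * sy
        nodata = np.nan
        if _TAG_GDAL_NODATA in tags:
            raw = str(tags[_TAG_GDAL_NODATA].value).strip()
            nodata = float("nan") if raw.lower() == "nan" else float(raw)
        desc = page.tags.get("ImageDescription")
        crs_id, source_tag = "", "SYNTH"
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                crs_id = meta.get("crs_id", "")
                source_tag = meta.get("source_tag", "SYNTH")
            except (TypeError, json.JSONDecodeError):
                pass
    if not crs_id:
        raise RasterError(f"missing CRS identifier in {path}")
    if math.isnan(nodata):
        mask = ~np.isfinite(arr)
    else:
        mask = (~np.isfinite(arr)) | (arr == nodata)
    arr = arr.copy()
    arr[mask] = np.nan
    return Grid(values=arr, transform=(float(x0), float(y0), float(sx)),
                crs_id=crs_id, nodata_mask=mask, source_tag=source_tag)


def read_reefs_geojson(path: str | Path, crs_id: str = "") -> ReefSet:
    """Load reef polygons from a GeoJSON FeatureCollection.

    Each feature must carry ``reef_id`` and may carry ``tide_station_id``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    reefs = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {}) or {}
        rid = str(props.get("reef_id", props.get("id", len(reefs))))
        station = str(props.get("tide_station_id", rid))
        reefs.append((rid, _shapely_shape(feat["geometry"]), station))
    return ReefSet(reefs=reefs)


def write_reefs_geojson(reefs: ReefSet, path: str | Path) -> Path:
    feats = [
        {
            "type": "Feature",
            "properties": {"reef_id": rid, "tide_station_id": station},
            "geometry": json.loads(shapely.to_geojson(poly)),
        }
        for rid, poly, station in reefs
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return Path(path)


# ---------------------------------------------------------------------------
# ACA-style preprocessing
# ---------------------------------------------------------------------------

def preprocess_aca(raw: Grid, fallback: Grid, divisor: float = -100.0) -> Grid:
    """Convert raw positive-down integer depths to metres and fill gaps.

    Values are divided by ``divisor`` (default −100: centimetres positive-down
    to metres negative-down).  Nodata cells with at least one valid 3x3
    neighbour are filled with the mean of the valid neighbours in a single
    pass reading only original values; remaining gaps come from ``fallback``,
    which must be aligned to ``raw``.
    """
    if raw.shape != fallback.shape or not np.allclose(raw.transform, fallback.transform):
        raise RasterError("fallback grid not aligned to raw grid")
    if raw.nodata_mask.all():
        raise RasterError("all-nodata input")
    valid = raw.valid_mask
    vals = np.where(valid, raw.values / divisor, 0.0)

    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nb_sum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)

    out = np.where(valid, raw.values / divisor, np.nan)
    fill_local = (~valid) & (nb_cnt > 0)
    out[fill_local] = nb_sum[fill_local] / nb_cnt[fill_local]
    fill_fb = (~valid) & (nb_cnt == 0) & fallback.valid_mask
    out[fill_fb] = fallback.values[fill_fb]
    mask = ~np.isfinite(out)
    out[mask] = np.nan
    n_local, n_fb = int(fill_local.sum()), int(fill_fb.sum())
    logger.info("preprocess_aca: %d cells filled locally, %d from fallback, %d left nodata",
                n_local, n_fb, int(mask.sum()))
    return Grid(values=out, transform=raw.transform, crs_id=raw.crs_id,
                nodata_mask=mask, source_tag=raw.source_tag)


def crop_to_reefs(grid: Grid, reefs: ReefSet, buffer_m: float = 500.0) -> Dict[str, Grid]:
    """Crop a grid to each reef polygon buffered by ``buffer_m``.

    The window snaps outward to whole pixels; cell centres outside the
    buffered polygon are masked.  Reefs disjoint from the grid are logged and
    skipped; an empty overall result raises.
    """
    if buffer_m < 0:
        raise RasterError("buffer_m must be >= 0")
    x0, y0, px = grid.transform
    nr, nc = grid.shape
    out: Dict[str, Grid] = {}
    for rid, poly, _ in reefs:
        buffered = poly.buffer(buffer_m) if buffer_m > 0 else poly
        minx, miny, maxx, maxy = buffered.bounds
        c0 = max(0, int(math.floor((minx - x0) / px)))
        c1 = min(nc, int(math.ceil((maxx - x0) / px)))
        r0 = max(0, int(math.floor((y0 - maxy) / px)))
        r1 = min(nr, int(math.ceil((y0 - miny) / px)))
        if c1 <= c0 or r1 <= r0:
            logger.warning("reef %s is disjoint from the grid; skipped", rid)
            continue
        sub = grid.values[r0:r1, c0:c1].copy()
        submask = grid.nodata_mask[r0:r1, c0:c1].copy()
        xs = x0 + (np.arange(c0, c1) + 0.5) * px
        ys = y0 - (np.arange(r0, r1) + 0.5) * px
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.intersects_xy(buffered, gx.ravel(), gy.ravel()).reshape(sub.shape)
        submask |= ~inside
        if submask.all():
            logger.warning("reef %s has no valid cells after crop; skipped", rid)
            continue
        sub[submask] = np.nan
        out[rid] = Grid(values=sub, transform=(x0 + c0 * px, y0 - r0 * px, px),
                        crs_id=grid.crs_id, nodata_mask=submask, source_tag=grid.source_tag)
    if not out:
        raise RasterError("no reef intersects the grid")
    return out


# ---------------------------------------------------------------------------
# Gaussian pyramid
# ---------------------------------------------------------------------------

def gaussian_reduce(grid: Grid) -> Grid:
    """One pyramid REDUCE step: 5-tap binomial smoothing then 2x decimation.

    Reflect padding at edges; nodata cells are excluded from the kernel and
    the remaining weights renormalised.  An output cell is nodata only if all
    contributing cells are nodata.  The origin is kept (even rows/cols are
    retained) and the pixel size doubles.
    """
    nr, nc = grid.shape
    if nr < 2 or nc < 2:
        raise RasterError(f"grid too small to reduce: {grid.shape}")
    kern2d = np.outer(PYRAMID_KERNEL_1D, PYRAMID_KERNEL_1D)
    valid = grid.valid_mask.astype(float)
    vals = np.where(grid.valid_mask, grid.values, 0.0)
    num = ndimage.correlate(vals, kern2d, mode="reflect")
    den = ndimage.correlate(valid, kern2d, mode="reflect")
    num, den = num[::2, ::2], den[::2, ::2]
    mask = den <= 1e-12
    out = np.full(num.shape, np.nan)
    out[~mask] = num[~mask] / den[~mask]
    x0, y0, px = grid.transform
    return Grid(values=out, transform=(x0, y0, 2.0 * px), crs_id=grid.crs_id,
                nodata_mask=mask, source_tag=grid.source_tag)


def build_dem_set(aca15: Grid, dr30: Grid, dr100: Grid) -> MultiscaleStack:
    """Build the canonical eight-DEM nested stack from the three sources.

    15 m source reduced to 30/60/120 m, 30 m source to 60/120 m, 100 m source
    passed through unchanged.
    """
    for grid, tag, res in ((aca15, "ACA", 15), (dr30, "DR30", 30), (dr100, "DR100", 100)):
        if not math.isclose(grid.pixel_size, res, rel_tol=1e-6):
            raise RasterError(
                f"{tag} input must be at {res} m resolution, found {grid.pixel_size} m")
    crs = {aca15.crs_id, dr30.crs_id, dr100.crs_id}
    if len(crs) > 1:
        raise RasterError(f"inputs mix CRS ids: {sorted(crs)}")

    levels: Dict[Tuple[str, int], Grid] = {}
    for tag, base in (("ACA", aca15), ("DR30", dr30)):
        g = replace(base, source_tag=tag)
        for res in NESTING_SCHEME[tag]:
            if not math.isclose(g.pixel_size, res, rel_tol=1e-6):
                g = gaussian_reduce(g)
            levels[(tag, res)] = g
    levels[("DR100", 100)] = replace(dr100, source_tag="DR100")
    stack = MultiscaleStack(levels=levels)
    stack.validate()
    assert len(stack) == 8
    return stack
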