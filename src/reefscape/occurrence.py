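"""Occurrence thinning, biased background sampling and predictor extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import Grid, RasterError
from .terrain import VariableStack, layer_name, parse_layer_name

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence or background points with reef labels."""

    species_code: str
    points: pd.DataFrame  # columns: point_id, x, y, reef_id
    role: str  # "presence" | "background"

    def __post_init__(self) -> None:
        if self.role not in ("presence", "background"):
            raise ValueError(f"bad role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)


def thin_occurrences(points: pd.DataFrame, ref_grid: Grid,
                     species_code: str = "SP") -> OccurrenceSet:
    """Retain one record per occupied reference-grid pixel.

    Points off-grid or on nodata cells are dropped (logged).  The survivor in
    each pixel is the first in a stable sort by record_id, so thinning is
    deterministic and idempotent.
    """
    df = points.copy()
    if "record_id" not in df.columns:
        df["record_id"] = np.arange(len(df))
    row, col = ref_grid.cell_of(df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float))
    on_grid = ref_grid.inside(row, col)
    valid = on_grid.copy()
    valid[on_grid] &= ~ref_grid.nodata_mask[row[on_grid], col[on_grid]]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("thin_occurrences: dropped %d points off valid cells", n_dropped)
    df = df.loc[valid].assign(_row=row[valid], _col=col[valid])
    if df.empty:
        raise RasterError("no occurrence points fall on valid reference cells")
    df = df.sort_values("record_id", kind="stable")
    thinned = df.drop_duplicates(subset=["_row", "_col"], keep="first")
    logger.info("thin_occurrences: %d -> %d records (%d occupied pixels)",
                len(points), len(thinned), len(thinned))
    out = thinned.drop(columns=["_row", "_col"]).reset_index(drop=True)
    out = out.rename(columns={"record_id": "point_id"})
    keep = [c for c in ("point_id", "x", "y", "reef_id") if c in out.columns]
    return OccurrenceSet(species_code=species_code, points=out[keep], role="presence")


def sample_background(all_coords: np.ndarray, reef_grids: Mapping[str, Grid],
                      n: int = 10000, bias_bandwidth_m: float = 500.0,
                      seed: int | None = None, epsilon: float = 0.05,
                      species_code: str = "SP") -> OccurrenceSet:
    """Draw ``n`` background points biased toward sampling intensity.

    Candidate cells are the union of valid cells across ``reef_grids``; each
    cell's weight is a Gaussian kernel density of ``all_coords`` (bandwidth
    ``bias_bandwidth_m``) plus a floor of ``epsilon`` times the maximum
    density.  Cells are drawn with replacement (points at cell centres), so
    exactly ``n`` points are returned; sampling is reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xs, ys, reef_ids = [], [], []
    for rid, grid in reef_grids.items():
        gx, gy = grid.cell_centers()
        ok = grid.valid_mask
        xs.append(gx[ok])
        ys.append(gy[ok])
        reef_ids.extend([rid] * int(ok.sum()))
    if not xs or sum(a.size for a in xs) == 0:
        raise RasterError("no valid reef cells to sample background from")
    cx = np.concatenate(xs)
    cy = np.concatenate(ys)
    reef_arr = np.asarray(reef_ids)

    coords = np.asarray(all_coords, dtype=float).reshape(-1, 2)
    density = np.zeros(cx.size)
    if coords.shape[0] > 0 and bias_bandwidth_m > 0 and np.isfinite(bias_bandwidth_m):
        # truncated Gaussian kernel sum; 4 bandwidths captures >0.9999 of mass
        tree = cKDTree(coords)
        cutoff = 4.0 * bias_bandwidth_m
        cells = np.column_stack([cx, cy])
        inv2b2 = 1.0 / (2.0 * bias_bandwidth_m**2)
        neighbours = tree.query_ball_point(cells, r=cutoff)
        for i, idx in enumerate(neighbours):
            if idx:
                d2 = np.sum((coords[idx] - cells[i]) ** 2, axis=1)
                density[i] = np.exp(-d2 * inv2b2).sum()
    dmax = density.max()
    weights = density + (epsilon * dmax if dmax > 0 else 1.0)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    pick = rng.choice(cx.size, size=n, replace=True, p=weights)
    points = pd.DataFrame({
        "point_id": [f"bg{i}" for i in range(n)],
        "x": cx[pick], "y": cy[pick], "reef_id": reef_arr[pick],
    })
    return OccurrenceSet(species_code=species_code, points=points, role="background")


def extract_values(points: pd.DataFrame, stack: VariableStack,
                   keys: Sequence[tuple] | Sequence[str] | None = None) -> pd.DataFrame:
    """Nearest-cell predictor extraction into a model-ready feature table.

    ``keys`` may be layer tuples or names; default is every layer in the
    stack.  Rows with any nodata value among the selected layers are dropped
    (counted in the log).  The returned frame keeps point_id/reef_id/label
    columns when present in ``points``.
    """
    if keys is None:
        keys = sorted(stack.keys())
    keys = [parse_layer_name(k) if isinstance(k, str) else tuple(k) for k in keys]
    missing = [k for k in keys if k not in stack]
    if missing:
        raise KeyError(f"layers not in stack: {missing}")
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    out = {}
    for key in keys:
        out[layer_name(key)] = stack[key].sample(x, y)
    feat = pd.DataFrame(out, index=points.index)
    meta_cols = [c for c in ("point_id", "reef_id", "label") if c in points.columns]
    table = pd.concat([points[meta_cols], feat], axis=1)
    ok = np.isfinite(feat.to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("extract_values: dropped %d rows with nodata", n_dropped)
    return table.loc[ok].reset_index(drop=True)


def build_feature_table(presences: OccurrenceSet, background: OccurrenceSet,
                        stack: VariableStack,
                        keys: Sequence | None = None) -> pd.DataFrame:
    """Stack presence (label 1) and background (label 0) rows and extract."""
    pres = presences.points.assign(label=1)
    bg = background.points.assign(label=0)
    combined = pd.concat([pres, bg], ignore_index=True)
    return extract_values(combined, stack, keys)
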