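"""Tide correction of field depths and DEM vertical-error summaries.

Field depths (positive metres below the surface at observation time) are
standardised to lowest astronomical tide: lat_depth = -(raw_depth + tide),
with tide height linearly interpolated in time from the reef's station.
Vertical error per record is dh = lat_depth - DEM value at the containing
cell, so a DEM shallower than the in-situ measurement gives negative dh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .grid import Grid

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["record_id", "reef_id", "x", "y", "raw_depth", "timestamp", "species_code"]


@dataclass
class TideTable:
    """Ordered tide-height samples (metres above LAT) for one station."""

    station_id: str
    times: np.ndarray  # seconds (monotone increasing)
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.size != self.heights.size:
            raise ValueError("times and heights differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"tide times not strictly increasing for {self.station_id}")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError(f"non-finite tide heights for {self.station_id}")

    def height_at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; NaN outside the series span."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.heights)
        out = np.where((t < self.times[0]) | (t > self.times[-1]), np.nan, out)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"station_id": self.station_id, "time": self.times,
                             "height": self.heights})


@dataclass
class ErrorSummary:
    """Robust and classical summaries of a vertical-error vector."""

    n: int
    median_dh: float
    sd_dh: float
    nmad: float
    rmse: float
    outlier_idx: List[int]
    qq_theoretical: np.ndarray
    qq_sampled: np.ndarray

    def to_dict(self) -> dict:
        return {"n": self.n, "median_dh": self.median_dh, "sd_dh": self.sd_dh,
                "nmad": self.nmad, "rmse": self.rmse,
                "n_outliers": len(self.outlier_idx)}


def correct_to_lat(records: pd.DataFrame, tides: Mapping[str, TideTable],
                   stations: Mapping[str, str]) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Add a ``lat_depth`` column (negative elevation, m) to depth records.

    ``stations`` maps reef_id -> station_id.  Records whose timestamp falls
    outside their station's tide series are excluded and returned separately.
    """
    recs = records.copy()
    lat = np.full(len(recs), np.nan)
    for reef_id, station_id in stations.items():
        sel = recs["reef_id"] == reef_id
        if not sel.any():
            continue
        tide = tides[station_id].height_at(recs.loc[sel, "timestamp"].to_numpy(dtype=float))
        lat[sel.to_numpy()] = -(recs.loc[sel, "raw_depth"].to_numpy(dtype=float) + tide)
    recs["lat_depth"] = lat
    bad = ~np.isfinite(lat)
    if bad.any():
        logger.warning("correct_to_lat: excluded %d records outside tide series span",
                       int(bad.sum()))
    return recs.loc[~bad].reset_index(drop=True), recs.loc[bad].reset_index(drop=True)


def vertical_error(records: pd.DataFrame, dem: Grid) -> Tuple[np.ndarray, int]:
    """dh_i = lat_depth_i - DEM(cell containing point i).

    Points on nodata cells or off-grid are excluded; their count is returned.
    Raises if every point misses the DEM.
    """
    if "lat_depth" not in records.columns:
        raise ValueError("records lack a lat_depth column; run correct_to_lat first")
    dem_vals = dem.sample(records["x"].to_numpy(dtype=float),
                          records["y"].to_numpy(dtype=float))
    ok = np.isfinite(dem_vals)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all points fall outside valid DEM cells")
    dh = records["lat_depth"].to_numpy(dtype=float)[ok] - dem_vals[ok]
    return dh, n_excluded


def summarize_error(dh: np.ndarray) -> ErrorSummary:
    """Median, SD, NMAD, RMSE, 3xRMSE outliers and normal Q-Q pairs of dh.

    NMAD = 1.4826 * median(|dh - median(dh)|); outliers satisfy
    |dh| > 3 * RMSE.  Q-Q theoretical quantiles come from a normal with the
    sample's mean and SD at plotting positions (k - 0.5)/n.
    """
    from scipy import stats

    dh = np.asarray(dh, dtype=float)
    if dh.size < 2:
        raise ValueError(f"need at least 2 errors, got {dh.size}")
    med = float(np.median(dh))
    sd = float(np.std(dh, ddof=1))
    nmad = float(1.4826 * np.median(np.abs(dh - med)))
    rmse = float(np.sqrt(np.mean(dh**2)))
    outliers = np.flatnonzero(np.abs(dh) > 3.0 * rmse).tolist()
    n = dh.size
    pp = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(pp, loc=float(np.mean(dh)), scale=sd if sd > 0 else 1.0)
    if sd == 0:
        theo = np.full(n, float(np.mean(dh)))
    return ErrorSummary(n=n, median_dh=med, sd_dh=sd, nmad=nmad, rmse=rmse,
                        outlier_idx=outliers, qq_theoretical=theo,
                        qq_sampled=np.sort(dh))


def assess_stack(records: pd.DataFrame, stack) -> pd.DataFrame:
    """ErrorSummary per (source, resolution) DEM level, as a tidy frame."""
    rows = []
    for (src, res), dem in stack.items():
        try:
            dh, n_excl = vertical_error(records, dem)
        except ValueError:
            continue
        if dh.size < 2:
            continue
        summ = summarize_error(dh)
        rows.append({"source": src, "resolution_m": res, "n_excluded": n_excl,
                     **summ.to_dict()})
    return pd.DataFrame(rows)


def read_tides_csv(path) -> Dict[str, TideTable]:
    """Load tide tables from CSV with columns station_id, time, height."""
    df = pd.read_csv(path)
    out = {}
    for sid, sub in df.groupby("station_id"):
        sub = sub.sort_values("time")
        out[str(sid)] = TideTable(station_id=str(sid),
                                  times=sub["time"].to_numpy(dtype=float),
                                  heights=sub["height"].to_numpy(dtype=float))
    return out


def write_tides_csv(tides: Mapping[str, TideTable], path) -> None:
    pd.concat([t.to_frame() for t in tides.values()]).to_csv(path, index=False)
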