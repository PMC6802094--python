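"""Annual robust-minimum composites of vegetation-index time series.

A year's "brownest" (EVI) or "driest" (NDII) composite is the mean of its
lowest 20% of valid index values (k = ceil(0.2 * n_valid), at least one
observation), stamped with the mean fractional-year timestamp of that
subset. Averaging the lowest fifth instead of taking the absolute minimum
damps observation noise in the annual peak-dry-season estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .config import AnalysisConfig
from .indices import IndexStack
from .raster import EPOCH_ORIGIN_YEAR, SceneGrid


def robust_annual_minimum(
    values: np.ndarray,
    timestamps: np.ndarray,
    fraction: float = 0.20,
    timestamp_mode: str = "subset-mean",
) -> Optional[Tuple[float, float]]:
    """Robust minimum of one pixel-year of observations.

    Parameters
    ----------
    values, timestamps
        1-D arrays of index values and fractional-year timestamps for one
        pixel within one calendar year; NaN values are invalid.
    fraction
        Fraction of the lowest valid values to average.
    timestamp_mode
        "subset-mean": mean timestamp of the averaged subset (default);
        "argmin": timestamp of the single smallest observation.

    Returns ``(value, timestamp)`` or ``None`` when no observation is valid.
    Ties at the k-th smallest value are broken by earliest timestamp.
    """
    values = np.asarray(values, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    ok = np.isfinite(values)
    n_valid = int(ok.sum())
    if n_valid == 0:
        return None
    v, t = values[ok], timestamps[ok]
    order = np.lexsort((t, v))  # value first, earliest timestamp on ties
    k = max(1, math.ceil(fraction * n_valid))
    sel = order[:k]
    if timestamp_mode == "argmin":
        ts = float(t[order[0]])
    elif timestamp_mode == "subset-mean":
        ts = float(t[sel].mean())
    else:
        raise ValueError(f"unknown timestamp_mode {timestamp_mode!r}")
    return float(v[sel].mean()), ts


@dataclass
class AnnualCompositeSeries:
    """Per-pixel annual composite values and timestamps for both tracks.

    ``values[track]`` and ``stamps[track]`` are (Y, H, W) arrays with NaN
    marking absent (fully masked) pixel-years; ``n_valid[track]`` counts the
    valid observations entering each pixel-year.
    """

    grid: SceneGrid
    years: np.ndarray  # (Y,) calendar years, strictly increasing
    values: Dict[str, np.ndarray]
    stamps: Dict[str, np.ndarray]
    n_valid: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.ndim != 1 or (self.years.size > 1 and np.any(np.diff(self.years) <= 0)):
            raise ValueError("years must be 1-D and strictly increasing")


def _year_composite(
    values: np.ndarray,
    times: np.ndarray,
    fraction: float,
    timestamp_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized robust minimum over the leading (observation) axis.

    ``values`` is (T, H, W) with NaN invalid; ``times`` is (T,). Relies on a
    stable sort over chronologically ordered observations for the
    earliest-timestamp tie-break.
    """
    T = values.shape[0]
    n_valid = np.isfinite(values).sum(axis=0)
    v = np.where(np.isfinite(values), values, np.inf)
    order = np.argsort(v, axis=0, kind="stable")
    sorted_v = np.take_along_axis(v, order, axis=0)
    t_full = np.broadcast_to(times[:, None, None], values.shape)
    sorted_t = np.take_along_axis(t_full, order, axis=0)

    k = np.maximum(1, np.ceil(fraction * n_valid).astype(int))
    k_idx = np.clip(k - 1, 0, T - 1)[None, ...]
    csum_v = np.cumsum(np.where(np.isfinite(sorted_v), sorted_v, 0.0), axis=0)
    csum_t = np.cumsum(sorted_t, axis=0)
    val = np.take_along_axis(csum_v, k_idx, axis=0)[0] / k
    if timestamp_mode == "argmin":
        ts = sorted_t[0]
    else:
        ts = np.take_along_axis(csum_t, k_idx, axis=0)[0] / k
    absent = n_valid == 0
    val = np.where(absent, np.nan, val)
    ts = np.where(absent, np.nan, ts)
    return val, ts, n_valid


def build_composites(
    index_stack: IndexStack,
    years: np.ndarray | range | None = None,
    config: AnalysisConfig | None = None,
) -> AnnualCompositeSeries:
    """Annual brownest/driest composites for every pixel and year.

    ``years`` defaults to the calendar years spanned by the stack; an empty
    range is an error.
    """
    cfg = config or AnalysisConfig()
    obs_years = np.floor(index_stack.times).astype(int) + EPOCH_ORIGIN_YEAR
    if years is None:
        years = np.arange(obs_years.min(), obs_years.max() + 1)
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("empty year range")

    shape = (years.size,) + index_stack.grid.shape
    values = {tr: np.full(shape, np.nan) for tr in ("brownest", "driest")}
    stamps = {tr: np.full(shape, np.nan) for tr in ("brownest", "driest")}
    n_valid = {tr: np.zeros(shape, dtype=int) for tr in ("brownest", "driest")}

    for yi, year in enumerate(years):
        in_year = obs_years == year
        if not in_year.any():
            continue
        t = index_stack.times[in_year]
        for track, arr in index_stack.tracks.items():
            val, ts, nv = _year_composite(
                arr[in_year], t, cfg.robust_min_fraction, cfg.composite_timestamp
            )
            values[track][yi] = val
            stamps[track][yi] = ts
            n_valid[track][yi] = nv

    return AnnualCompositeSeries(
        grid=index_stack.grid, years=years, values=values, stamps=stamps, n_valid=n_valid
    )
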