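"""Per-pixel robust trend estimation within before/after epochs.

Slopes of annual composite change are estimated with Sen's nonparametric
estimator — the median of all pairwise slopes (y_j - y_i)/(x_j - x_i),
robust to outlying years — against the composites' fractional-year
timestamps. Siegel's repeated-medians variant is available as an option.
Pixels with fewer than 5 valid composite years in an epoch are dropped;
a PA with more than 20% of its area dropped in an epoch is excluded from
analyses involving that epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .composites import AnnualCompositeSeries
from .config import AnalysisConfig

TRACKS = ("brownest", "driest")
EPOCH_LABELS = ("before", "after")


@dataclass(frozen=True)
class Epoch:
    """Inclusive calendar-year range labelled before/after declaration."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"epoch label must be one of {EPOCH_LABELS}")
        if self.end < self.start:
            raise ValueError("epoch end before start")

    def contains(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years)
        return (years >= self.start) & (years <= self.end)

    @property
    def n_years(self) -> int:
        return self.end - self.start + 1


def epochs_for(
    declaration_year: int,
    years: Sequence[int],
    config: AnalysisConfig | None = None,
) -> dict[str, Epoch]:
    """Split a year range into before/after epochs at the declaration year.

    By default the declaration year opens the "after" epoch (protection
    takes effect in the year it is conferred). Either epoch may be absent
    when the declaration falls at the edge of the record.
    """
    cfg = config or AnalysisConfig()
    years = np.asarray(list(years), dtype=int)
    y0, y1 = int(years.min()), int(years.max())
    if not (y0 <= declaration_year <= y1 + 1):
        raise ValueError(
            f"declaration year {declaration_year} outside series range {y0}-{y1}"
        )
    split = declaration_year if cfg.declaration_year_in_after else declaration_year + 1
    out: dict[str, Epoch] = {}
    if split - 1 >= y0:
        out["before"] = Epoch("before", y0, split - 1)
    if split <= y1:
        out["after"] = Epoch("after", split, y1)
    return out


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(len(x), k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = dx != 0
    return dy[keep] / dx[keep]


def sen_slope(
    points: Iterable[Tuple[float, float]] | None = None,
    *,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    estimator: str = "theil-sen",
) -> float:
    """Sen's slope of a small series, as (x, y) arrays or (x, y) pairs.

    "theil-sen": median over all pairwise slopes with distinct abscissae.
    "siegel": median over points i of the median slope from point i to all
    others (repeated medians). All-equal abscissae raise ValueError.
    """
    if points is not None:
        pts = np.asarray(list(points), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (x, y) pairs")
        x, y = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.all(x == x[0]):
        raise ValueError("slope undefined: all timestamps equal")
    if estimator == "theil-sen":
        return float(np.median(_pairwise_slopes(x, y)))
    if estimator == "siegel":
        inner = []
        for i in range(x.size):
            dx = np.delete(x, i) - x[i]
            dy = np.delete(y, i) - y[i]
            keep = dx != 0
            if not keep.any():
                continue
            inner.append(np.median(dy[keep] / dx[keep]))
        return float(np.median(inner))
    raise ValueError(f"unknown estimator {estimator!r}")


def _sen_slope_map(
    values: np.ndarray, stamps: np.ndarray, min_points: int, estimator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Sen slope over the leading (year) axis.

    ``values`` and ``stamps`` are (Y, H, W); NaN marks absent years.
    Returns (slope, valid) where slope is NaN at pixels with fewer than
    ``min_points`` valid years.
    """
    Y = values.shape[0]
    finite = np.isfinite(values) & np.isfinite(stamps)
    n_years = finite.sum(axis=0)
    valid = n_years >= min_points

    if estimator == "siegel":  # per-pixel loop; used only on small scenes
        slope = np.full(values.shape[1:], np.nan)
        for idx in np.argwhere(valid):
            r, c = idx
            ok = finite[:, r, c]
            slope[r, c] = sen_slope(
                x=stamps[ok, r, c], y=values[ok, r, c], estimator="siegel"
            )
        return slope, valid

    i, j = np.triu_indices(Y, k=1)
    dv = values[j] - values[i]
    dt = stamps[j] - stamps[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        pair = np.where(dt != 0, dv / dt, np.nan)
    slope = np.nanmedian(pair, axis=0) if pair.size else np.full(values.shape[1:], np.nan)
    slope = np.where(valid, slope, np.nan)
    return slope, valid


def pixel_validity(
    series: AnnualCompositeSeries,
    epoch: Epoch,
    track: str = "brownest",
    min_points: int = 5,
) -> np.ndarray:
    """Pixels with at least ``min_points`` valid composite years in the epoch."""
    in_epoch = epoch.contains(series.years)
    if not in_epoch.any():
        return np.zeros(series.grid.shape, dtype=bool)
    n = np.isfinite(series.values[track][in_epoch]).sum(axis=0)
    return n >= min_points


def pa_sufficiency(
    validity_mask: np.ndarray,
    pa_mask: np.ndarray,
    max_insufficient_fraction: float = 0.20,
) -> bool:
    """Whether a PA has enough well-observed area in an epoch.

    Retained iff the fraction of PA pixels lacking a valid trend is at most
    ``max_insufficient_fraction`` (strictly more drops the PA).
    """
    pa_mask = np.asarray(pa_mask, dtype=bool)
    n_pa = int(pa_mask.sum())
    if n_pa == 0:
        raise ValueError("empty PA mask")
    insufficient = np.asarray(~validity_mask, dtype=bool) & pa_mask
    return bool(insufficient.sum() / n_pa <= max_insufficient_fraction)


@dataclass
class SlopeMaps:
    """Per-pixel Sen slopes for each (track, epoch) with validity masks.

    ``slopes[(track, epoch_label)]`` is (H, W) in index units per year,
    NaN where the pixel had insufficient data in that epoch.
    """

    grid: object
    epochs: Dict[str, Epoch]
    slopes: Dict[Tuple[str, str], np.ndarray]
    valid: Dict[Tuple[str, str], np.ndarray]

    def validity_all(self, epoch_labels: Iterable[str]) -> np.ndarray:
        """Pixels with valid slopes in both tracks for all given epochs."""
        out = np.ones(next(iter(self.valid.values())).shape, dtype=bool)
        for lab in epoch_labels:
            for track in TRACKS:
                out &= self.valid[(track, lab)]
        return out


def estimate_epoch_slopes(
    composites: AnnualCompositeSeries,
    declaration_year: int,
    config: AnalysisConfig | None = None,
) -> SlopeMaps:
    """Sen slopes of both composite tracks within each epoch.

    The regression abscissa is the composite's fractional-year timestamp,
    not the integer year, so intra-annual timing of the dry-season minimum
    carries through to the trend estimate.
    """
    cfg = config or AnalysisConfig()
    epochs = epochs_for(declaration_year, composites.years, cfg)
    slopes: Dict[Tuple[str, str], np.ndarray] = {}
    valid: Dict[Tuple[str, str], np.ndarray] = {}
    for label, epoch in epochs.items():
        in_epoch = epoch.contains(composites.years)
        for track in TRACKS:
            s, v = _sen_slope_map(
                composites.values[track][in_epoch],
                composites.stamps[track][in_epoch],
                cfg.min_points_per_epoch,
                cfg.estimator,
            )
            slopes[(track, label)] = s
            valid[(track, label)] = v
    return SlopeMaps(grid=composites.grid, epochs=epochs, slopes=slopes, valid=valid)
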