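"""Minimal raster containers: a projected scene grid, a dated multiband
reflectance stack with a quality layer, and a monthly precipitation grid.

Coordinates are planar (metres, north-up). Time is expressed as fractional
years since 1984-01-01, the start of the satellite record the pipeline is
designed around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

EPOCH_ORIGIN_YEAR = 1984

BANDS = ("blue", "red", "nir", "swir1")

# QA codes
QA_CLEAR = 0
QA_CLOUD = 1
QA_WATER = 2


@dataclass(frozen=True)
class SceneGrid:
    """North-up rectangular pixel grid in projected coordinates.

    ``origin`` is the (x, y) of the grid's upper-left corner; row index
    increases southward, column index eastward.
    """

    width: int
    height: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of shape (height, width) with pixel-center coords."""
        ox, oy = self.origin
        xs = ox + (np.arange(self.width) + 0.5) * self.pixel_size
        ys = oy - (np.arange(self.height) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def rasterize(self, geometry: BaseGeometry) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside ``geometry``."""
        if geometry is None or geometry.is_empty:
            return np.zeros(self.shape, dtype=bool)
        if not geometry.is_valid:
            raise ValueError("cannot rasterize an invalid geometry")
        x, y = self.pixel_centers()
        return shapely.contains_xy(geometry, x, y)

    def extent_polygon(self) -> BaseGeometry:
        ox, oy = self.origin
        return box(
            ox, oy - self.height * self.pixel_size, ox + self.width * self.pixel_size, oy
        )

    @classmethod
    def covering(
        cls, geometry: BaseGeometry, n_pixels: int = 48, pad_fraction: float = 0.05
    ) -> "SceneGrid":
        """Square grid of ``n_pixels`` per side covering ``geometry``'s
        padded bounding box.  Used to give every PA its own analysis grid."""
        minx, miny, maxx, maxy = geometry.bounds
        side = max(maxx - minx, maxy - miny) * (1 + 2 * pad_fraction)
        if side <= 0:
            raise ValueError("degenerate geometry bounds")
        cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
        pixel = side / n_pixels
        origin = (cx - side / 2, cy + side / 2)
        return cls(width=n_pixels, height=n_pixels, pixel_size=pixel, origin=origin)


def fractional_year(year: np.ndarray | float, within: np.ndarray | float) -> np.ndarray:
    """Fractional years since Jan 1 of the origin year, given a calendar
    year and a within-year fraction in [0, 1)."""
    return np.asarray(year, dtype=float) - EPOCH_ORIGIN_YEAR + np.asarray(within, float)


@dataclass
class ReflectanceStack:
    """Dated multiband surface-reflectance observations on a scene grid.

    Attributes
    ----------
    grid : SceneGrid
    times : (T,) fractional years since 1984-01-01, strictly increasing
    bands : dict band name -> (T, H, W) float reflectance in [0, 1]
    qa : (T, H, W) uint8, one of QA_CLEAR / QA_CLOUD / QA_WATER
    valid : (T, H, W) bool; starts all-True, set by QA masking
    """

    grid: SceneGrid
    times: np.ndarray
    bands: Dict[str, np.ndarray]
    qa: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        shape = (self.times.size,) + self.grid.shape
        for name in BANDS:
            if name not in self.bands:
                raise ValueError(f"missing band {name!r}")
            if self.bands[name].shape != shape:
                raise ValueError(f"band {name!r} has shape {self.bands[name].shape}, expected {shape}")
        if self.qa.shape != shape:
            raise ValueError("qa shape mismatch")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)

    @property
    def n_dates(self) -> int:
        return int(self.times.size)

    @property
    def years(self) -> np.ndarray:
        """Calendar year of every observation date."""
        return np.floor(self.times).astype(int) + EPOCH_ORIGIN_YEAR

    def copy(self) -> "ReflectanceStack":
        return ReflectanceStack(
            grid=self.grid,
            times=self.times.copy(),
            bands={k: v.copy() for k, v in self.bands.items()},
            qa=self.qa.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class PrecipGrid:
    """Monthly-mean precipitation climatology on a coarse north-up grid.

    ``monthly`` is (12, H, W) in mm per month; cellwise annual total is the
    sum over the 12 monthly means.
    """

    monthly: np.ndarray
    origin: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        self.monthly = np.asarray(self.monthly, dtype=float)
        if self.monthly.ndim != 3 or self.monthly.shape[0] != 12:
            raise ValueError("monthly must have shape (12, H, W)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def annual(self) -> np.ndarray:
        return self.monthly.sum(axis=0)

    def cell_polygon(self, row: int, col: int) -> BaseGeometry:
        ox, oy = self.origin
        x0 = ox + col * self.cell_size
        y1 = oy - row * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.monthly.shape[1:]


# ---------------------------------------------------------------------------
# Raster serialization (plain TIFF via tifffile; grid georeferencing in a
# JSON sidecar so round trips stay text-inspectable)
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, array: np.ndarray, grid: SceneGrid) -> None:
    import json

    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array))
    sidecar = {
        "width": grid.width,
        "height": grid.height,
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path: str | Path) -> tuple[np.ndarray, SceneGrid]:
    import json

    import tifffile

    path = Path(path)
    array = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = SceneGrid(
        width=meta["width"],
        height=meta["height"],
        pixel_size=meta["pixel_size"],
        origin=tuple(meta["origin"]),
    )
    return array, grid
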