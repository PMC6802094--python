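"""Synthetic scenes, reflectance stacks and PA tables with known truth.

The generator emulates the structure of a long single-sensor satellite
record over Indian protected areas: irregular within-year observation
dates, cloud/water-masked gaps, additive observation noise on vegetation
indices, and piecewise-linear per-epoch trends in each pixel's annual
minimum EVI and NDII. Index values are generated first and then inverted
exactly to reflectance bands (blue and red held at plausible constants,
NIR solved from the EVI target, SWIR1 from the NDII target given that
NIR), so the planted slope is the literal ground truth of the quantity the
pipeline estimates.

The within-year observation-date pattern is drawn once per scene and
repeated every year. With a fixed annual pattern the same observations are
selected into the robust minimum each year, so at zero noise the composite
series is exactly linear with the planted slope — the generator's truth is
sharp rather than approximate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from shapely.geometry import box

from . import baci
from .matching import PARecord, PATable, STATUS_TR, STATUS_WLS
from .raster import (
    BANDS,
    EPOCH_ORIGIN_YEAR,
    PrecipGrid,
    QA_CLEAR,
    QA_CLOUD,
    QA_WATER,
    ReflectanceStack,
    SceneGrid,
)

logger = logging.getLogger(__name__)

TRACKS = ("brownest", "driest")

# Generator study conditions -------------------------------------------------
#: Fixed blue and red reflectances used in the exact index inversion.
BLUE_REFLECTANCE = 0.05
RED_REFLECTANCE = 0.10
#: Dry-season trough ("intercept") index levels at the start of the record.
BASE_LEVEL = {"brownest": 0.45, "driest": 0.25}
#: Seasonal amplitude added on top of the annual minimum (greener/wetter
#: parts of the year sit above the dry-season trough).
SEASONAL_AMPLITUDE = {"brownest": 0.25, "driest": 0.20}
#: Within-year position of the dry-season trough (late pre-monsoon).
SEASONAL_TROUGH = 0.35
#: Long-term mean annual rainfall range (mm/yr) for generated PAs.
RAINFALL_RANGE = (600.0, 3000.0)
#: Area ranges (km^2) for generated impact and control PAs.
TR_AREA_RANGE = (140.0, 2600.0)
WLS_AREA_RANGE = (30.0, 1200.0)
#: Range of TR declaration years.
DECLARATION_RANGE = (1986, 2000)
#: Default per-pixel trend magnitude range (index units / yr).
SLOPE_RANGE = (0.002, 0.008)

_EVI_COEF = (2.5, 6.0, 7.5, 1.0)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    years is an inclusive (first, last) calendar-year range; obs_per_year
    approximates the satellite revisit cadence (about 23 for a 16-day
    orbit). cloud_fraction / water_fraction are independent per-observation
    masking probabilities; noise_sd is additive index-space noise.
    """

    width: int = 48
    height: int = 48
    pixel_size: float = 30.0
    origin: Tuple[float, float] = (0.0, 0.0)
    years: Tuple[int, int] = (1984, 2012)
    obs_per_year: int = 23
    cloud_fraction: float = 0.0
    water_fraction: float = 0.0
    noise_sd: float = 0.0
    declaration_year: int = 1993
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene dimensions must be >= 1")
        if self.years[1] - self.years[0] + 1 < 2:
            raise ValueError("scene must span at least 2 years")
        if self.obs_per_year < 1:
            raise ValueError("obs_per_year must be >= 1")
        for name in ("cloud_fraction", "water_fraction"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cloud_fraction + self.water_fraction > 1:
            raise ValueError("cloud_fraction + water_fraction must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.years[0] <= self.declaration_year <= self.years[1]:
            raise ValueError("declaration_year must fall inside the year range")

    @property
    def grid(self) -> SceneGrid:
        return SceneGrid(
            width=self.width,
            height=self.height,
            pixel_size=self.pixel_size,
            origin=self.origin,
        )

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


@dataclass
class TruthMap:
    """Planted per-pixel trend structure and its implied categories.

    slope_before / slope_after map each track to an (H, W) array of true
    index-units-per-year slopes. The category properties apply the same
    sign rules the analysis uses, so the truth labels are by construction
    those implied by the signed slopes.
    """

    slope_before: Dict[str, np.ndarray]
    slope_after: Dict[str, np.ndarray]
    base_level: Dict[str, float] = field(
        default_factory=lambda: dict(BASE_LEVEL)
    )

    def condition_categories(self) -> np.ndarray:
        """True after-epoch condition labels (improve/decline/unclear)."""
        return np.asarray(
            baci.classify_after(
                self.slope_after["brownest"], self.slope_after["driest"]
            )
        )

    def change_categories(self) -> np.ndarray:
        """True before-to-after change labels (helped/harmed/unclear)."""
        return np.asarray(
            baci.classify_change(
                self.slope_before["brownest"],
                self.slope_after["brownest"],
                self.slope_before["driest"],
                self.slope_after["driest"],
            )
        )


def make_truth(
    shape: Tuple[int, int],
    slope_after: Dict[str, np.ndarray | float],
    slope_before: Dict[str, np.ndarray | float] | None = None,
) -> TruthMap:
    """TruthMap from explicit slopes (scalars broadcast over the scene)."""

    def expand(d: Dict[str, np.ndarray | float] | None) -> Dict[str, np.ndarray]:
        d = d or {}
        return {
            tr: np.broadcast_to(np.asarray(d.get(tr, 0.0), dtype=float), shape).copy()
            for tr in TRACKS
        }

    after = expand(slope_after)
    for tr in TRACKS:
        if not np.all(np.isfinite(after[tr])):
            raise ValueError("target slopes must be finite")
    return TruthMap(slope_before=expand(slope_before), slope_after=after)


def random_truth(
    spec: SceneSpec,
    condition_fractions: Tuple[float, float, float] = (0.4, 0.4, 0.2),
    change_fractions: Optional[Tuple[float, float, float]] = None,
    slope_range: Tuple[float, float] = SLOPE_RANGE,
    seed: Optional[int] = None,
) -> TruthMap:
    """Plant per-pixel slopes realizing target category fractions.

    condition_fractions = (improve, decline, unclear) shares of pixels for
    the after epoch; change_fractions, when given, similarly controls the
    sign of the before-to-after slope differences (otherwise before slopes
    are zero and change categories coincide with condition categories).
    """
    if not math.isclose(sum(condition_fractions), 1.0, abs_tol=1e-9):
        raise ValueError("condition_fractions must sum to 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed if seed is None else seed, 1])
    )
    shape = (spec.height, spec.width)
    n = shape[0] * shape[1]

    def signed_pair(fractions: Tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray]:
        cats = rng.choice(3, size=n, p=list(fractions))
        mag_b = rng.uniform(*slope_range, size=n)
        mag_d = rng.uniform(*slope_range, size=n)
        sign_b = np.where(cats == 0, 1.0, -1.0)
        sign_d = np.where(cats == 0, 1.0, -1.0)
        flip = rng.random(n) < 0.5  # unclear pixels: (+,-) or (-,+)
        sign_b[cats == 2] = np.where(flip[cats == 2], 1.0, -1.0)
        sign_d[cats == 2] = -sign_b[cats == 2]
        return (sign_b * mag_b).reshape(shape), (sign_d * mag_d).reshape(shape)

    after_b, after_d = signed_pair(condition_fractions)
    slope_after = {"brownest": after_b, "driest": after_d}
    if change_fractions is None:
        slope_before = {tr: np.zeros(shape) for tr in TRACKS}
    else:
        if not math.isclose(sum(change_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("change_fractions must sum to 1")
        diff_b, diff_d = signed_pair(change_fractions)
        slope_before = {
            "brownest": after_b - diff_b,
            "driest": after_d - diff_d,
        }
    return TruthMap(slope_before=slope_before, slope_after=slope_after)


def _observation_times(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Fractional-year timestamps, same within-year pattern every year."""
    n = spec.obs_per_year
    base = (np.arange(n) + 0.5) / n
    jitter = rng.uniform(-0.25, 0.25, size=n) / n
    offsets = np.sort(np.clip(base + jitter, 0.0, 1.0 - 1e-9))
    years = np.arange(spec.years[0], spec.years[1] + 1) - EPOCH_ORIGIN_YEAR
    return (years[:, None] + offsets[None, :]).ravel()


def _seasonal(offset_within_year: np.ndarray, track: str) -> np.ndarray:
    """Non-negative seasonal excursion above the dry-season trough."""
    u = np.asarray(offset_within_year)
    return SEASONAL_AMPLITUDE[track] * 0.5 * (
        1.0 - np.cos(2.0 * np.pi * (u - SEASONAL_TROUGH))
    )


def _piecewise_trend(
    times: np.ndarray, split: float, base: float, s_before: np.ndarray, s_after: np.ndarray
) -> np.ndarray:
    """Continuous piecewise-linear trough level: slope switches at split.

    ``times`` is (T,), slopes are (H, W); result is (T, H, W). The trend is
    anchored so the trough level equals ``base`` at the split time.
    """
    t = times[:, None, None]
    before = base + s_before[None] * (t - split)
    after = base + s_after[None] * (t - split)
    return np.where(t < split, before, after)


def _invert_evi(evi: np.ndarray) -> np.ndarray:
    g, c1, c2, soil = _EVI_COEF
    return (g * RED_REFLECTANCE + evi * (c1 * RED_REFLECTANCE - c2 * BLUE_REFLECTANCE + soil)) / (
        g - evi
    )


def _invert_ndii(ndii: np.ndarray, nir: np.ndarray) -> np.ndarray:
    return nir * (1.0 - ndii) / (1.0 + ndii)


def generate_stack(
    spec: SceneSpec, truth: TruthMap
) -> ReflectanceStack:
    """Reflectance stack whose annual index minima follow the planted trends.

    Deterministic (bit-reproducible) for a fixed (spec, truth). Reflectances
    falling outside [0, 1] are clipped with a logged warning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    times = _observation_times(spec, rng)
    offsets = times - np.floor(times)
    split = float(spec.declaration_year - EPOCH_ORIGIN_YEAR)
    shape = (times.size, spec.height, spec.width)

    index_values: Dict[str, np.ndarray] = {}
    for track in TRACKS:
        trend = _piecewise_trend(
            times,
            split,
            truth.base_level[track],
            truth.slope_before[track],
            truth.slope_after[track],
        )
        values = trend + _seasonal(offsets, track)[:, None, None]
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=shape)
        index_values[track] = values

    nir = _invert_evi(index_values["brownest"])
    swir1 = _invert_ndii(index_values["driest"], nir)
    bands = {
        "blue": np.full(shape, BLUE_REFLECTANCE),
        "red": np.full(shape, RED_REFLECTANCE),
        "nir": nir,
        "swir1": swir1,
    }
    n_clipped = int(np.count_nonzero((nir < 0) | (nir > 1) | (swir1 < 0) | (swir1 > 1)))
    if n_clipped:
        logger.warning(
            "clipped %d reflectance values outside [0, 1]; planted slopes "
            "exceed the representable index range there",
            n_clipped,
        )
        bands["nir"] = np.clip(nir, 0.0, 1.0)
        bands["swir1"] = np.clip(swir1, 0.0, 1.0)

    u = rng.random(size=shape)
    qa = np.full(shape, QA_CLEAR, dtype=np.uint8)
    qa[u < spec.cloud_fraction] = QA_CLOUD
    qa[(u >= spec.cloud_fraction) & (u < spec.cloud_fraction + spec.water_fraction)] = QA_WATER

    return ReflectanceStack(grid=spec.grid, times=times, bands=bands, qa=qa)


def simulate_scene(
    spec: SceneSpec, truth: TruthMap | None = None, **truth_kwargs
) -> tuple[ReflectanceStack, TruthMap]:
    """Convenience: (stack, truth) with a random truth when none is given."""
    if truth is None:
        truth = random_truth(spec, **truth_kwargs)
    return generate_stack(spec, truth), truth


# ---------------------------------------------------------------------------
# PA table and precipitation grid generation
# ---------------------------------------------------------------------------

_STATE_BLOCK_KM = 400.0
_STATE_GAP_KM = 100.0


def _rect_geometry(
    rng: np.random.Generator, state_index: int, area_km2: float
):
    """Axis-aligned rectangle of the given area inside the state's block."""
    aspect = rng.uniform(0.5, 2.0)
    w_km = math.sqrt(area_km2 * aspect)
    h_km = area_km2 / w_km
    x0_state = state_index * (_STATE_BLOCK_KM + _STATE_GAP_KM)
    max_x = _STATE_BLOCK_KM - w_km
    max_y = _STATE_BLOCK_KM - h_km
    if max_x < 0 or max_y < 0:  # PA larger than block; pin to corner
        max_x = max(max_x, 0.0)
        max_y = max(max_y, 0.0)
    x = x0_state + rng.uniform(0, max_x if max_x > 0 else 1e-9)
    y = rng.uniform(0, max_y if max_y > 0 else 1e-9)
    m = 1000.0  # km -> metres
    return box(x * m, y * m, (x + w_km) * m, (y + h_km) * m)


def generate_pa_table(
    n_states: int, n_tr: int, n_wls: int, seed: int
) -> PATable:
    """Random PA attribute table with rectangular footprints.

    States occupy disjoint square blocks of a planar map (so same-state PAs
    are near each other and cross-state distances are large). TRs draw
    areas from the impact-PA size range and declaration years from
     1986-2000; WLS areas draw from the control range, with the first WLS
    of every state forced to at least the 75 km^2 matching floor so each
    state retains an admissible control. Deterministic for a fixed seed.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_tr < 0 or n_wls < 0:
        raise ValueError("PA counts must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    states = [f"S{i+1:02d}" for i in range(n_states)]
    records = []
    first_wls_in_state: set[int] = set()
    for k in range(n_tr):
        si = k % n_states
        area = rng.uniform(*TR_AREA_RANGE)
        records.append(
            PARecord(
                id=f"TR{k+1:03d}",
                name=f"Tiger Reserve {k+1}",
                status=STATUS_TR,
                state=states[si],
                area_km2=float(area),
                rainfall_mm=float(rng.uniform(*RAINFALL_RANGE)),
                declaration_year=int(rng.integers(DECLARATION_RANGE[0], DECLARATION_RANGE[1] + 1)),
                geometry=_rect_geometry(rng, si, area),
            )
        )
    for k in range(n_wls):
        si = k % n_states
        area = rng.uniform(*WLS_AREA_RANGE)
        if si not in first_wls_in_state:
            area = max(area, 75.0 + rng.uniform(0, 200.0))
            first_wls_in_state.add(si)
        records.append(
            PARecord(
                id=f"WLS{k+1:03d}",
                name=f"Wildlife Sanctuary {k+1}",
                status=STATUS_WLS,
                state=states[si],
                area_km2=float(area),
                rainfall_mm=float(rng.uniform(*RAINFALL_RANGE)),
                declaration_year=None,
                geometry=_rect_geometry(rng, si, area),
            )
        )
    return PATable(records)


def generate_precip_grid(
    table: PATable, cell_size_km: float = 50.0, seed: int = 0
) -> PrecipGrid:
    """Smooth monthly precipitation climatology covering a PA table.

    Annual totals vary smoothly across the map within the generator's
    rainfall range; a monsoon-shaped monthly profile distributes each
    cell's annual total over the 12 months.
    """
    if len(table) == 0:
        raise ValueError("empty PA table")
    import shapely

    bounds = shapely.unary_union([r.geometry for r in table]).bounds
    m = 1000.0
    pad = cell_size_km * m
    minx, miny, maxx, maxy = (
        bounds[0] - pad,
        bounds[1] - pad,
        bounds[2] + pad,
        bounds[3] + pad,
    )
    cell = cell_size_km * m
    ncol = max(1, math.ceil((maxx - minx) / cell))
    nrow = max(1, math.ceil((maxy - miny) / cell))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    xs = (np.arange(ncol) + 0.5) / ncol
    ys = (np.arange(nrow) + 0.5) / nrow
    X, Y = np.meshgrid(xs, ys)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    field01 = 0.5 + 0.25 * np.sin(2 * np.pi * X + phase[0]) + 0.25 * np.cos(
        2 * np.pi * Y + phase[1]
    )
    lo, hi = RAINFALL_RANGE
    annual = lo + (hi - lo) * field01
    # monsoon-shaped monthly profile peaking mid-year
    month = np.arange(12)
    profile = np.exp(-0.5 * ((month - 6.5) / 1.8) ** 2)
    profile = profile / profile.sum()
    monthly = annual[None, :, :] * profile[:, None, None]
    return PrecipGrid(monthly=monthly, origin=(minx, maxy), cell_size=cell)
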