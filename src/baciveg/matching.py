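"""Control-impact matching of protected areas.

Each Tiger Reserve (TR, impact) is matched to a Wildlife Sanctuary (WLS,
control) that (i) lies in the same state, (ii) has area >= 75 km^2,
(iii) has long-term mean annual rainfall within 500 mm of the TR's, and
(iv) is the nearest such WLS. When two TRs claim the same WLS, the TR
processed earlier (ascending declaration year, then id) keeps it and the
other falls back to its next-nearest candidate, so WLS assignments stay
distinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .config import AnalysisConfig
from .raster import PrecipGrid

STATUS_TR = "TR"
STATUS_WLS = "WLS"


@dataclass
class PARecord:
    """One protected area's attributes and footprint.

    ``area_km2`` and ``rainfall_mm`` are matching covariates; geometry is in
    planar metres. ``declaration_year`` is meaningful for TRs only (controls'
    declaration years play no role in the design).
    """

    id: str
    name: str
    status: str  # TR | WLS | other
    state: str
    area_km2: float
    rainfall_mm: float
    declaration_year: Optional[int]
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"PA {self.id}: area must be positive")
        if self.rainfall_mm < 0:
            raise ValueError(f"PA {self.id}: rainfall must be non-negative")


@dataclass
class PATable:
    """Ordered collection of PARecords with tabular/GeoJSON round trips."""

    records: List[PARecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, pa_id: str) -> PARecord:
        for r in self.records:
            if r.id == pa_id:
                return r
        raise KeyError(pa_id)

    def by_status(self, status: str) -> List[PARecord]:
        return [r for r in self.records if r.status == status]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "name": r.name,
                    "status": r.status,
                    "state": r.state,
                    "area_km2": r.area_km2,
                    "rainfall_mm": r.rainfall_mm,
                    "declaration_year": r.declaration_year,
                }
                for r in self.records
            ]
        )

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "id": r.id,
                        "name": r.name,
                        "status": r.status,
                        "state": r.state,
                        "area_km2": r.area_km2,
                        "rainfall_mm": r.rainfall_mm,
                        "declaration_year": r.declaration_year,
                    },
                    "geometry": mapping(r.geometry),
                }
                for r in self.records
            ],
        }

    def write(self, csv_path: str | Path, geojson_path: str | Path) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        Path(geojson_path).write_text(json.dumps(self.to_geojson()))

    @classmethod
    def from_geojson(cls, geojson_path: str | Path) -> "PATable":
        data = json.loads(Path(geojson_path).read_text())
        records = []
        for feat in data["features"]:
            p = feat["properties"]
            year = p.get("declaration_year")
            records.append(
                PARecord(
                    id=str(p["id"]),
                    name=p.get("name", str(p["id"])),
                    status=p["status"],
                    state=p["state"],
                    area_km2=float(p["area_km2"]),
                    rainfall_mm=float(p["rainfall_mm"]),
                    declaration_year=None if year is None else int(year),
                    geometry=shape(feat["geometry"]),
                )
            )
        return cls(records)


@dataclass(frozen=True)
class MatchedPair:
    tr_id: str
    wls_id: str
    rainfall_difference_mm: float
    separation_distance_km: float


def pa_mean_rainfall(pa: PARecord | BaseGeometry, grid: PrecipGrid) -> float:
    """Area-weighted mean annual rainfall (mm/yr) over a PA polygon.

    The cellwise annual total (sum of the 12 monthly means) is averaged over
    the precipitation cells intersecting the polygon, weighted by
    intersection area. Raises when the polygon misses the grid entirely.
    """
    geom = pa.geometry if isinstance(pa, PARecord) else pa
    annual = grid.annual
    total_w = 0.0
    total = 0.0
    nrow, ncol = grid.shape
    minx, miny, maxx, maxy = geom.bounds
    ox, oy = grid.origin
    c0 = max(0, int((minx - ox) // grid.cell_size))
    c1 = min(ncol - 1, int((maxx - ox) // grid.cell_size))
    r0 = max(0, int((oy - maxy) // grid.cell_size))
    r1 = min(nrow - 1, int((oy - miny) // grid.cell_size))
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            w = grid.cell_polygon(r, c).intersection(geom).area
            if w > 0:
                total += w * annual[r, c]
                total_w += w
    if total_w == 0:
        raise ValueError("PA polygon does not overlap the precipitation grid")
    return total / total_w


def separation_distance(
    a: BaseGeometry, b: BaseGeometry, metric: str = "boundary"
) -> float:
    """Distance between two PA footprints in km.

    "boundary": minimum separation between the polygons (0 when they touch
    or overlap). "centroid": distance between centroids.
    """
    for g in (a, b):
        if g is None or g.is_empty or not g.is_valid:
            raise ValueError("invalid geometry")
    if metric == "boundary":
        d = a.distance(b)
    elif metric == "centroid":
        d = a.centroid.distance(b.centroid)
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    return d / 1000.0


def candidate_wls(
    tr: PARecord, table: PATable, config: AnalysisConfig | None = None
) -> List[PARecord]:
    """Controls admissible for a given TR: same state, area >= floor,
    rainfall within the window (all bounds inclusive)."""
    cfg = config or AnalysisConfig()
    return [
        r
        for r in table.by_status(STATUS_WLS)
        if r.state == tr.state
        and r.area_km2 >= cfg.wls_min_area_km2
        and abs(r.rainfall_mm - tr.rainfall_mm) <= cfg.rainfall_window_mm
    ]


def match_pairs(
    table: PATable, config: AnalysisConfig | None = None
) -> Tuple[List[MatchedPair], List[str]]:
    """Assign each TR its nearest admissible WLS, injectively.

    TRs are processed in ascending (declaration_year, id); each takes its
    nearest not-yet-claimed candidate, so a later TR whose nearest control
    is already claimed falls back to its next-nearest. Returns the matched
    pairs (in processing order) and ids of TRs left unmatched.
    """
    cfg = config or AnalysisConfig()
    trs = sorted(
        table.by_status(STATUS_TR),
        key=lambda r: (
            r.declaration_year if r.declaration_year is not None else 10**9,
            r.id,
        ),
    )
    taken: set[str] = set()
    pairs: List[MatchedPair] = []
    unmatched: List[str] = []
    for tr in trs:
        cands = [
            (separation_distance(tr.geometry, w.geometry, cfg.distance_metric), w.id, w)
            for w in candidate_wls(tr, table, cfg)
            if w.id not in taken
        ]
        if not cands:
            unmatched.append(tr.id)
            continue
        cands.sort(key=lambda t: (t[0], t[1]))  # distance, id for determinism
        dist, _, wls = cands[0]
        taken.add(wls.id)
        pairs.append(
            MatchedPair(
                tr_id=tr.id,
                wls_id=wls.id,
                rainfall_difference_mm=abs(tr.rainfall_mm - wls.rainfall_mm),
                separation_distance_km=dist,
            )
        )
    return pairs, unmatched


def pairs_to_dataframe(pairs: Sequence[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tr_id": p.tr_id,
                "wls_id": p.wls_id,
                "rainfall_difference_mm": p.rainfall_difference_mm,
                "separation_distance_km": p.separation_distance_km,
            }
            for p in pairs
        ],
        columns=[
            "tr_id",
            "wls_id",
            "rainfall_difference_mm",
            "separation_distance_km",
        ],
    )
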