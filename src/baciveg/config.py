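"""Analysis configuration: every filtering and classification threshold in
one declarative place.

Defaults are the study design's published values: a 500 mm rainfall window
and 75 km^2 area floor for control matching, at least 5 valid composite
years per pixel per epoch, at most 20% of PA area with insufficient data,
the least-20% robust annual minimum, and a 15 percentage-point
substantiality threshold for matched-pair composition differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class AnalysisConfig:
    """Thresholds and method options for the BACI vegetation analysis.

    Parameters
    ----------
    rainfall_window_mm
        Maximum |mean-annual-rainfall difference| (mm/yr) between an impact
        PA and a candidate control.
    wls_min_area_km2
        Minimum area (km^2) of a candidate control PA.
    min_points_per_epoch
        Minimum number of valid annual composites a pixel needs within an
        epoch for its trend to be estimated; pixels below it are dropped.
    max_insufficient_fraction
        A PA whose insufficient-pixel fraction in an epoch exceeds this is
        dropped from analyses involving that epoch (strictly greater drops).
    robust_min_fraction
        Fraction of a year's lowest valid index values averaged to form the
        robust annual minimum (k = ceil(fraction * n_valid), at least 1).
    substantial_threshold_pct
        Matched-pair composition difference (percentage points of PA area,
        in improvement or decline) at or above which the pair difference is
        called substantial.
    declaration_year_in_after
        If True (default) the declaration year opens the "after" epoch;
        otherwise it closes the "before" epoch.
    estimator
        "theil-sen" (median of all pairwise slopes; default) or "siegel"
        (repeated medians).
    distance_metric
        "boundary" (minimum separation; default) or "centroid" distance for
        control matching.
    composite_timestamp
        "subset-mean" (mean timestamp of the averaged lowest-k subset;
        default) or "argmin" (timestamp of the single minimum).
    evi_coefficients
        (G, C1, C2, L) of the soil/atmosphere-adjusted EVI formula.
    reflectance_scale
        "unit" for reflectances in [0, 1]; "scaled10000" for integer
        surface-reflectance products stored as reflectance x 10000.
    """

    rainfall_window_mm: float = 500.0
    wls_min_area_km2: float = 75.0
    min_points_per_epoch: int = 5
    max_insufficient_fraction: float = 0.20
    robust_min_fraction: float = 0.20
    substantial_threshold_pct: float = 15.0
    declaration_year_in_after: bool = True
    estimator: str = "theil-sen"
    distance_metric: str = "boundary"
    composite_timestamp: str = "subset-mean"
    evi_coefficients: Tuple[float, float, float, float] = (2.5, 6.0, 7.5, 1.0)
    reflectance_scale: str = "unit"

    def validate(self) -> list[str]:
        """Return a list of human-readable problems; empty when valid."""
        errors: list[str] = []
        if not self.rainfall_window_mm > 0:
            errors.append("rainfall_window_mm must be positive")
        if not self.wls_min_area_km2 > 0:
            errors.append("wls_min_area_km2 must be positive")
        if self.min_points_per_epoch < 2:
            errors.append("min_points_per_epoch must be at least 2")
        if not 0 < self.max_insufficient_fraction <= 1:
            errors.append("max_insufficient_fraction must be in (0, 1]")
        if not 0 < self.robust_min_fraction <= 1:
            errors.append("robust_min_fraction must be in (0, 1]")
        if not self.substantial_threshold_pct > 0:
            errors.append("substantial_threshold_pct must be positive")
        if self.estimator not in ("theil-sen", "siegel"):
            errors.append(f"unknown estimator {self.estimator!r}")
        if self.distance_metric not in ("boundary", "centroid"):
            errors.append(f"unknown distance_metric {self.distance_metric!r}")
        if self.composite_timestamp not in ("subset-mean", "argmin"):
            errors.append(
                f"unknown composite_timestamp {self.composite_timestamp!r}"
            )
        if len(self.evi_coefficients) != 4:
            errors.append("evi_coefficients must be (G, C1, C2, L)")
        if self.reflectance_scale not in ("unit", "scaled10000"):
            errors.append(f"unknown reflectance_scale {self.reflectance_scale!r}")
        return errors

    def require_valid(self) -> "AnalysisConfig":
        problems = self.validate()
        if problems:
            raise ValueError("invalid AnalysisConfig: " + "; ".join(problems))
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["evi_coefficients"] = list(self.evi_coefficients)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "evi_coefficients" in d:
            d["evi_coefficients"] = tuple(d["evi_coefficients"])
        return cls(**d)
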