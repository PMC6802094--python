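"""Vegetation indices: EVI (greenness) and NDII (canopy moisture).

EVI = G * (NIR - Red) / (NIR + C1*Red - C2*Blue + L) with the standard
(G, C1, C2, L) = (2.5, 6, 7.5, 1) parameterization; NDII is the normalized
difference of NIR and the 1.55-1.75 um shortwave infrared band. Invalid
observations (masked, or with a singular denominator) are carried as NaN
rather than raised, so whole stacks can be processed vectorially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import AnalysisConfig
from .raster import QA_CLEAR, ReflectanceStack, SceneGrid

logger = logging.getLogger(__name__)

#: EVI values outside this range are flagged invalid: surface-reflectance
#: artifacts can make the rational formula arbitrarily large, and a single
#: artifact would otherwise capture the annual minimum.
EVI_CLAMP = (-1.0, 2.0)

_DENOM_TOL = 1e-12


def compute_evi(
    blue: np.ndarray | float,
    red: np.ndarray | float,
    nir: np.ndarray | float,
    coefficients: Tuple[float, float, float, float] = (2.5, 6.0, 7.5, 1.0),
) -> np.ndarray | float:
    """Enhanced vegetation index; NaN where any input is NaN, the
    denominator is ~0, or the result falls outside ``EVI_CLAMP``."""
    g, c1, c2, soil = coefficients
    blue = np.asarray(blue, dtype=float)
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = nir + c1 * red - c2 * blue + soil
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = np.where(np.abs(denom) < _DENOM_TOL, np.nan, g * (nir - red) / denom)
    evi = np.where((evi < EVI_CLAMP[0]) | (evi > EVI_CLAMP[1]), np.nan, evi)
    return evi if evi.ndim else float(evi)


def compute_ndii(
    nir: np.ndarray | float, swir1: np.ndarray | float
) -> np.ndarray | float:
    """Normalized difference infrared index (NIR - SWIR1)/(NIR + SWIR1);
    NaN where any input is NaN or NIR + SWIR1 = 0."""
    nir = np.asarray(nir, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    denom = nir + swir1
    with np.errstate(divide="ignore", invalid="ignore"):
        ndii = np.where(np.abs(denom) < _DENOM_TOL, np.nan, (nir - swir1) / denom)
    return ndii if ndii.ndim else float(ndii)


def apply_qa_mask(stack: ReflectanceStack) -> ReflectanceStack:
    """Mark cloud- and water-flagged observations invalid.

    Returns a new stack whose ``valid`` layer is the conjunction of the
    input validity and QA == clear; clear observations are untouched, so
    the operation is idempotent. Per-date drop counts are logged.
    """
    if stack.qa is None:
        raise ValueError("stack has no QA layer")
    out = stack.copy()
    clear = stack.qa == QA_CLEAR
    newly_dropped = out.valid & ~clear
    out.valid &= clear
    for t in range(stack.n_dates):
        n = int(newly_dropped[t].sum())
        if n:
            logger.debug("t=%.3f: masked %d cloud/water observations", stack.times[t], n)
    logger.info(
        "QA masking dropped %d of %d observations",
        int(newly_dropped.sum()),
        int(newly_dropped.size),
    )
    return out


@dataclass
class IndexStack:
    """Per-date EVI and NDII values with a shared validity mask.

    ``evi`` and ``ndii`` are (T, H, W) with NaN at invalid observations;
    ``times`` are fractional years since 1984-01-01.
    """

    grid: SceneGrid
    times: np.ndarray
    evi: np.ndarray
    ndii: np.ndarray

    @property
    def tracks(self) -> dict[str, np.ndarray]:
        """Index arrays keyed by composite track: ``brownest`` uses EVI,
        ``driest`` uses NDII."""
        return {"brownest": self.evi, "driest": self.ndii}


def compute_index_stack(
    stack: ReflectanceStack, config: AnalysisConfig | None = None
) -> IndexStack:
    """EVI and NDII for every observation in a (QA-masked) stack."""
    cfg = config or AnalysisConfig()
    scale = 1e-4 if cfg.reflectance_scale == "scaled10000" else 1.0
    b = {k: stack.bands[k] * scale for k in ("blue", "red", "nir", "swir1")}
    evi = np.asarray(compute_evi(b["blue"], b["red"], b["nir"], cfg.evi_coefficients))
    ndii = np.asarray(compute_ndii(b["nir"], b["swir1"]))
    invalid = ~stack.valid
    evi = np.where(invalid, np.nan, evi)
    ndii = np.where(invalid, np.nan, ndii)
    return IndexStack(grid=stack.grid, times=stack.times, evi=evi, ndii=ndii)
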