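"""Condition classification, PA composition summaries and matched-pair
comparison.

A pixel's after-declaration condition is classified from the signs of its
two after-epoch slopes: both positive -> "improve", both negative ->
"decline", mixed -> "unclear". Its condition *change* is classified the
same way from the before-to-after slope differences: both positive ->
"helped", both negative -> "harmed". Zero slopes or differences fall to
"unclear" (the strict-inequality rules leave them undefined); pixels
missing any required slope are "insufficient".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .trends import SlopeMaps


class Category(IntEnum):
    """Integer codes for condition / condition-change categories.

    POSITIVE reads "improve" in after-only mode and "helped" in
    before-after mode; NEGATIVE reads "decline"/"harmed".
    """

    INSUFFICIENT = 0
    POSITIVE = 1
    NEGATIVE = 2
    UNCLEAR = 3


AFTER_ONLY_LABELS = {
    Category.POSITIVE: "improve",
    Category.NEGATIVE: "decline",
    Category.UNCLEAR: "unclear",
    Category.INSUFFICIENT: "insufficient",
}
BEFORE_AFTER_LABELS = {
    Category.POSITIVE: "helped",
    Category.NEGATIVE: "harmed",
    Category.UNCLEAR: "unclear",
    Category.INSUFFICIENT: "insufficient",
}


def _classify_signs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sign-pair classification shared by both rule sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.full(np.broadcast(a, b).shape, int(Category.UNCLEAR), dtype=np.uint8)
    out[(a > 0) & (b > 0)] = Category.POSITIVE
    out[(a < 0) & (b < 0)] = Category.NEGATIVE
    out[np.isnan(a) | np.isnan(b)] = Category.INSUFFICIENT
    return out


def classify_after(
    s_b_after: np.ndarray | float, s_d_after: np.ndarray | float
) -> np.ndarray | Category:
    """After-epoch condition from brownest/driest slope signs."""
    out = _classify_signs(s_b_after, s_d_after)
    return out if out.ndim else Category(int(out))


def classify_change(
    s_b_before: np.ndarray | float,
    s_b_after: np.ndarray | float,
    s_d_before: np.ndarray | float,
    s_d_after: np.ndarray | float,
) -> np.ndarray | Category:
    """Before-to-after condition change from slope-difference signs."""
    db = np.asarray(s_b_after, float) - np.asarray(s_b_before, float)
    dd = np.asarray(s_d_after, float) - np.asarray(s_d_before, float)
    out = _classify_signs(db, dd)
    return out if out.ndim else Category(int(out))


def classify_maps(slope_maps: SlopeMaps, mode: str) -> np.ndarray:
    """Category map for a whole scene in "after-only" or "before-after" mode."""
    if mode == "after-only":
        return np.asarray(
            classify_after(
                slope_maps.slopes[("brownest", "after")],
                slope_maps.slopes[("driest", "after")],
            )
        )
    if mode == "before-after":
        for lab in ("before", "after"):
            if lab not in slope_maps.epochs:
                raise ValueError(f"before-after mode requires a {lab!r} epoch")
        return np.asarray(
            classify_change(
                slope_maps.slopes[("brownest", "before")],
                slope_maps.slopes[("brownest", "after")],
                slope_maps.slopes[("driest", "before")],
                slope_maps.slopes[("driest", "after")],
            )
        )
    raise ValueError(f"unknown mode {mode!r}")


class PADroppedError(ValueError):
    """Raised when a composition is requested for a PA that failed the
    epoch data-sufficiency rule."""


@dataclass
class CompositionSummary:
    """Percentage of a PA's pixel area in each category.

    Percentages are over all PA pixels, so the insufficient share is
    visible; they sum to 100. ``mode`` selects the label vocabulary.
    """

    pa_id: str
    mode: str  # after-only | before-after
    percent: Dict[str, float]

    @property
    def positive(self) -> float:
        return self.percent["improve" if self.mode == "after-only" else "helped"]

    @property
    def negative(self) -> float:
        return self.percent["decline" if self.mode == "after-only" else "harmed"]


def composition(
    category_map: np.ndarray,
    pa_mask: np.ndarray,
    pa_id: str = "",
    mode: str = "after-only",
    sufficient: bool = True,
) -> CompositionSummary:
    """Category composition of a PA as percentages of its pixel count."""
    if not sufficient:
        raise PADroppedError(
            f"PA {pa_id!r} was dropped by the area-sufficiency rule; "
            "no composition is reported"
        )
    pa_mask = np.asarray(pa_mask, dtype=bool)
    n = int(pa_mask.sum())
    if n == 0:
        raise ValueError("empty PA mask")
    labels = AFTER_ONLY_LABELS if mode == "after-only" else BEFORE_AFTER_LABELS
    cats = np.asarray(category_map)[pa_mask]
    percent = {
        name: 100.0 * float(np.count_nonzero(cats == code)) / n
        for code, name in labels.items()
    }
    return CompositionSummary(pa_id=pa_id, mode=mode, percent=percent)


@dataclass(frozen=True)
class PairComparison:
    tr_id: str
    wls_id: str
    verdict: str  # better | worse | ambiguous
    substantial: bool
    delta_positive: float  # TR minus WLS, percentage points
    delta_negative: float


def compare_pair(
    tr: CompositionSummary,
    wls: CompositionSummary,
    config: AnalysisConfig | None = None,
) -> PairComparison:
    """Verdict on a matched pair from its two composition summaries.

    "better": the TR has strictly more area improving (helped) AND strictly
    less declining (harmed) than its control; "worse" is the reverse;
    anything else is "ambiguous". The difference is "substantial" when
    either category differs by at least the configured threshold
    (default 15 percentage points).
    """
    cfg = config or AnalysisConfig()
    if tr.mode != wls.mode:
        raise ValueError("composition summaries have different epoch modes")
    d_pos = tr.positive - wls.positive
    d_neg = tr.negative - wls.negative
    if d_pos > 0 and d_neg < 0:
        verdict = "better"
    elif d_pos < 0 and d_neg > 0:
        verdict = "worse"
    else:
        verdict = "ambiguous"
    substantial = (
        abs(d_pos) >= cfg.substantial_threshold_pct
        or abs(d_neg) >= cfg.substantial_threshold_pct
    )
    return PairComparison(
        tr_id=tr.pa_id,
        wls_id=wls.pa_id,
        verdict=verdict,
        substantial=substantial,
        delta_positive=d_pos,
        delta_negative=d_neg,
    )


def ternary_export(summaries: Sequence[CompositionSummary]) -> pd.DataFrame:
    """Compositions renormalized over the three analysed categories.

    Insufficient-data area is excluded and the positive/negative/unclear
    shares rescaled to sum to 1, the coordinates of a point in the
    3-simplex for ternary plotting.
    """
    rows = []
    for s in summaries:
        labels = AFTER_ONLY_LABELS if s.mode == "after-only" else BEFORE_AFTER_LABELS
        pos = s.positive
        neg = s.negative
        unc = s.percent["unclear"]
        tot = pos + neg + unc
        if tot <= 0:
            continue
        rows.append(
            {
                "pa_id": s.pa_id,
                labels[Category.POSITIVE]: pos / tot,
                labels[Category.NEGATIVE]: neg / tot,
                "unclear": unc / tot,
            }
        )
    return pd.DataFrame(rows)


def compositions_to_dataframe(summaries: Sequence[CompositionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"pa_id": s.pa_id, "mode": s.mode}
        row.update(s.percent)
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_to_dataframe(comps: Sequence[PairComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tr_id": c.tr_id,
                "wls_id": c.wls_id,
                "verdict": c.verdict,
                "substantial": c.substantial,
                "delta_positive_pct": c.delta_positive,
                "delta_negative_pct": c.delta_negative,
            }
            for c in comps
        ],
        columns=[
            "tr_id",
            "wls_id",
            "verdict",
            "substantial",
            "delta_positive_pct",
            "delta_negative_pct",
        ],
    )
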