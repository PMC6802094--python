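"""Model/results interface over the BACI vegetation-condition pipeline.

:class:`BACIModel` bundles a PA table, per-PA reflectance stacks and an
:class:`~baciveg.config.AnalysisConfig`; ``fit()`` performs control
matching, per-pixel composite and trend estimation, condition
classification and matched-pair comparison, returning a
:class:`BACIResults` with tabular results, per-PA maps and a ``summary()``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import baci
from .baci import CompositionSummary, PairComparison
from .composites import AnnualCompositeSeries, build_composites
from .config import AnalysisConfig
from .indices import apply_qa_mask, compute_index_stack
from .matching import MatchedPair, PATable, match_pairs, pairs_to_dataframe
from .raster import ReflectanceStack, SceneGrid
from .trends import SlopeMaps, estimate_epoch_slopes, pa_sufficiency
from .synthetic import SceneSpec, TruthMap, generate_pa_table, random_truth, generate_stack

#: provider(pa_id, declaration_year) -> (stack, pa_pixel_mask, truth-or-None)
StackProvider = Callable[
    [str, int], Tuple[ReflectanceStack, np.ndarray, Optional[TruthMap]]
]


@dataclass
class SceneAnalysis:
    """Per-pixel analysis of one PA's scene for one declaration year."""

    pa_id: str
    declaration_year: int
    slope_maps: SlopeMaps
    pa_mask: np.ndarray
    condition_map: np.ndarray  # after-only categories
    change_map: Optional[np.ndarray]  # before-after categories, when possible
    sufficiency: Dict[str, bool]  # epoch label -> PA retained?


def analyze_scene(
    stack: ReflectanceStack,
    declaration_year: int,
    pa_mask: Optional[np.ndarray] = None,
    pa_id: str = "",
    config: Optional[AnalysisConfig] = None,
) -> SceneAnalysis:
    """Full single-scene pipeline: QA mask -> indices -> annual robust-minimum
    composites -> per-epoch Sen slopes -> condition / change categories."""
    cfg = (config or AnalysisConfig()).require_valid()
    if pa_mask is None:
        pa_mask = np.ones(stack.grid.shape, dtype=bool)
    masked = apply_qa_mask(stack)
    index_stack = compute_index_stack(masked, cfg)
    composites = build_composites(index_stack, config=cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixel medians
        slope_maps = estimate_epoch_slopes(composites, declaration_year, cfg)

    sufficiency: Dict[str, bool] = {}
    for label in slope_maps.epochs:
        validity = slope_maps.validity_all([label])
        sufficiency[label] = pa_sufficiency(
            validity, pa_mask, cfg.max_insufficient_fraction
        )

    condition_map = baci.classify_maps(slope_maps, "after-only")
    change_map = None
    if "before" in slope_maps.epochs and "after" in slope_maps.epochs:
        change_map = baci.classify_maps(slope_maps, "before-after")
    return SceneAnalysis(
        pa_id=pa_id,
        declaration_year=declaration_year,
        slope_maps=slope_maps,
        pa_mask=pa_mask,
        condition_map=condition_map,
        change_map=change_map,
        sufficiency=sufficiency,
    )


class BACIModel:
    """Before-after-control-impact model of protection effects on
    vegetation condition.

    Parameters
    ----------
    pa_table
        Attribute table of impact (TR) and control (WLS) protected areas.
    stack_provider
        Callable ``(pa_id, declaration_year) -> (stack, pa_mask, truth)``
        supplying each analysed PA's dated reflectance stack and its pixel
        footprint on that stack's grid (truth may be None for real data).
    config
        Analysis thresholds and options; defaults to the published design.

    Examples
    --------
    >>> model = BACIModel.from_simulation(n_states=2, n_tr=3, n_wls=6, seed=42)
    >>> results = model.fit()
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        pa_table: PATable,
        stack_provider: StackProvider,
        config: Optional[AnalysisConfig] = None,
    ) -> None:
        self.pa_table = pa_table
        self.stack_provider = stack_provider
        self.config = (config or AnalysisConfig()).require_valid()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_simulation(
        cls,
        n_states: int = 2,
        n_tr: int = 3,
        n_wls: int = 6,
        seed: int = 0,
        scene_pixels: int = 32,
        years: Tuple[int, int] = (1984, 2012),
        obs_per_year: int = 12,
        cloud_fraction: float = 0.1,
        water_fraction: float = 0.02,
        noise_sd: float = 0.01,
        config: Optional[AnalysisConfig] = None,
    ) -> "BACIModel":
        """Model over a fully synthetic study: a random PA table plus, for
        every analysed PA, a simulated scene whose grid covers the PA's
        footprint at ``scene_pixels`` per side (grids are scaled to PA size
        rather than held at 30 m, keeping simulated studies desk-sized).
        Per-PA truth compositions are drawn from the per-PA random stream,
        so fixed (inputs, seed) reproduce the study bit-for-bit."""
        table = generate_pa_table(n_states, n_tr, n_wls, seed)

        def provider(pa_id: str, declaration_year: int):
            record = table.get(pa_id)
            grid = SceneGrid.covering(record.geometry, n_pixels=scene_pixels)
            pa_digest = zlib.crc32(pa_id.encode()) % (2**31)
            pa_seed = int(
                np.random.SeedSequence([seed, 5, pa_digest]).generate_state(1)[0]
                % (2**31)
            )
            spec = SceneSpec(
                width=grid.width,
                height=grid.height,
                pixel_size=grid.pixel_size,
                origin=grid.origin,
                years=years,
                obs_per_year=obs_per_year,
                cloud_fraction=cloud_fraction,
                water_fraction=water_fraction,
                noise_sd=noise_sd,
                declaration_year=declaration_year,
                seed=pa_seed,
            )
            rng = np.random.default_rng(np.random.SeedSequence([pa_seed, 4]))
            cond = rng.dirichlet([2.0, 2.0, 1.0])
            change = rng.dirichlet([2.0, 2.0, 1.0])
            truth = random_truth(
                spec,
                condition_fractions=tuple(cond),
                change_fractions=tuple(change),
            )
            stack = generate_stack(spec, truth)
            pa_mask = grid.rasterize(record.geometry)
            return stack, pa_mask, truth

        return cls(table, provider, config)

    # -- estimation ---------------------------------------------------------

    def fit(self) -> "BACIResults":
        """Match controls, analyse every matched PA's scene, and compare
        matched-pair compositions in after-only and (where both epochs have
        sufficient data) before-after modes."""
        cfg = self.config
        pairs, unmatched = match_pairs(self.pa_table, cfg)

        analyses: Dict[str, SceneAnalysis] = {}
        compositions: List[CompositionSummary] = []
        comparisons: Dict[str, List[PairComparison]] = {
            "after-only": [],
            "before-after": [],
        }
        dropped: List[tuple[str, str]] = []

        for pair in pairs:
            tr = self.pa_table.get(pair.tr_id)
            decl = tr.declaration_year
            if decl is None:
                raise ValueError(f"TR {tr.id} has no declaration year")
            pair_analyses = {}
            for pa_id in (pair.tr_id, pair.wls_id):
                stack, pa_mask, _truth = self.stack_provider(pa_id, decl)
                pair_analyses[pa_id] = analyze_scene(
                    stack, decl, pa_mask, pa_id=pa_id, config=cfg
                )
            analyses.update(pair_analyses)

            per_mode: Dict[str, Dict[str, CompositionSummary]] = {}
            for mode, map_attr, needed in (
                ("after-only", "condition_map", ("after",)),
                ("before-after", "change_map", ("before", "after")),
            ):
                ok = all(
                    all(a.sufficiency.get(lab, False) for lab in needed)
                    and getattr(a, map_attr) is not None
                    for a in pair_analyses.values()
                )
                if not ok:
                    for pa_id, a in pair_analyses.items():
                        if not all(a.sufficiency.get(lab, False) for lab in needed):
                            dropped.append((pa_id, mode))
                    continue
                per_mode[mode] = {
                    pa_id: baci.composition(
                        getattr(a, map_attr), a.pa_mask, pa_id=pa_id, mode=mode
                    )
                    for pa_id, a in pair_analyses.items()
                }
                compositions.extend(per_mode[mode].values())
                comparisons[mode].append(
                    baci.compare_pair(
                        per_mode[mode][pair.tr_id], per_mode[mode][pair.wls_id], cfg
                    )
                )

        return BACIResults(
            model=self,
            matched_pairs=pairs,
            unmatched_tr_ids=unmatched,
            analyses=analyses,
            compositions=compositions,
            comparisons=comparisons,
            dropped=dropped,
        )


@dataclass
class BACIResults:
    """Fitted BACI analysis: matches, per-PA maps, compositions, verdicts."""

    model: BACIModel
    matched_pairs: List[MatchedPair]
    unmatched_tr_ids: List[str]
    analyses: Dict[str, SceneAnalysis]
    compositions: List[CompositionSummary]
    comparisons: Dict[str, List[PairComparison]]
    dropped: List[tuple[str, str]] = field(default_factory=list)

    # -- tabular views ------------------------------------------------------

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return pairs_to_dataframe(self.matched_pairs)

    @property
    def compositions_frame(self) -> pd.DataFrame:
        return baci.compositions_to_dataframe(self.compositions)

    def comparisons_frame(self, mode: str = "after-only") -> pd.DataFrame:
        return baci.comparisons_to_dataframe(self.comparisons[mode])

    def ternary_frame(self, mode: str = "after-only") -> pd.DataFrame:
        return baci.ternary_export([c for c in self.compositions if c.mode == mode])

    # -- reporting ----------------------------------------------------------

    def verdict_counts(self, mode: str = "after-only") -> Dict[str, int]:
        out = {"better": 0, "worse": 0, "ambiguous": 0}
        for c in self.comparisons[mode]:
            out[c.verdict] += 1
        return out

    def summary(self) -> str:
        lines = []
        cfg = self.model.config
        lines.append("BACI vegetation-condition analysis")
        lines.append("=" * 50)
        lines.append(
            f"Protected areas: {len(self.model.pa_table)} "
            f"({len(self.model.pa_table.by_status('TR'))} TR, "
            f"{len(self.model.pa_table.by_status('WLS'))} WLS)"
        )
        lines.append(
            f"Matched pairs: {len(self.matched_pairs)}; "
            f"unmatched TRs: {len(self.unmatched_tr_ids)}"
        )
        lines.append(
            f"Estimator: {cfg.estimator}; min points/epoch: "
            f"{cfg.min_points_per_epoch}; max insufficient area: "
            f"{cfg.max_insufficient_fraction:.0%}"
        )
        for mode in ("after-only", "before-after"):
            comps = self.comparisons[mode]
            if not comps:
                lines.append(f"[{mode}] no pairs analysable")
                continue
            counts = self.verdict_counts(mode)
            n_sub = sum(c.substantial for c in comps)
            lines.append(
                f"[{mode}] {len(comps)} pairs: "
                f"{counts['better']} better, {counts['worse']} worse, "
                f"{counts['ambiguous']} ambiguous "
                f"({n_sub} substantial at >= {cfg.substantial_threshold_pct:g} pp)"
            )
        if self.dropped:
            lines.append(f"PA/mode combinations dropped for data: {len(self.dropped)}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_ternary(self, mode: str = "after-only", ax=None):
        """Compositions in the 3-simplex (positive / negative / unclear)."""
        import matplotlib.pyplot as plt

        df = self.ternary_frame(mode)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        cols = [c for c in df.columns if c != "pa_id"]
        if not df.empty:
            a, b, c = (df[col].to_numpy() for col in cols)
            x = 0.5 * (2 * b + c) / (a + b + c)
            y = (np.sqrt(3) / 2) * c / (a + b + c)
            ax.scatter(x, y)
            for xi, yi, pid in zip(x, y, df["pa_id"]):
                ax.annotate(pid, (xi, yi), fontsize=7)
        ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], "k-", lw=0.8)
        labels = cols if cols else ["positive", "negative", "unclear"]
        ax.text(-0.02, -0.04, labels[0], ha="right")
        ax.text(1.02, -0.04, labels[1], ha="left")
        ax.text(0.5, np.sqrt(3) / 2 + 0.03, labels[2], ha="center")
        ax.set_aspect("equal")
        ax.axis("off")
        return ax
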