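"""End-to-end pipeline orchestration: config file, staged runs, manifest.

A single YAML config declares the simulation conditions and every analysis
threshold; ``run_pipeline`` executes simulate -> indices -> composites ->
trends -> match -> classify -> report through :class:`baciveg.model.BACIModel`
and writes CSV/GeoJSON outputs plus a JSON run manifest. All randomness
flows from the config's single seed, so manifest-identical runs are
output-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .config import AnalysisConfig
from .model import BACIModel
from .raster import ReflectanceStack, SceneGrid, read_raster, write_raster

logger = logging.getLogger(__name__)

STAGES = ("simulate", "indices", "composites", "trends", "match", "classify", "report")

DEFAULT_SIMULATION = {
    "n_states": 2,
    "n_tr": 3,
    "n_wls": 6,
    "scene_pixels": 32,
    "years": [1984, 2012],
    "obs_per_year": 12,
    "cloud_fraction": 0.1,
    "water_fraction": 0.02,
    "noise_sd": 0.01,
}


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    config_path: str
    output_dir: str
    outputs: Dict[str, str]
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def load_config(config_path: str | Path) -> dict:
    raw = Path(config_path).read_text()
    cfg = yaml.safe_load(raw) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def validate_config(config_path: str | Path) -> List[str]:
    """Itemized config problems; empty list when the config is valid."""
    try:
        cfg = load_config(config_path)
    except Exception as exc:  # unreadable / unparsable
        return [f"cannot read config: {exc}"]
    errors: List[str] = []
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    sim = {**DEFAULT_SIMULATION, **cfg.get("simulation", {})}
    for key in ("n_states", "n_tr", "n_wls", "scene_pixels", "obs_per_year"):
        if not isinstance(sim[key], int) or sim[key] < 0:
            errors.append(f"simulation.{key} must be a non-negative integer")
    if isinstance(sim.get("n_states"), int) and sim["n_states"] < 1:
        errors.append("simulation.n_states must be >= 1")
    years = sim.get("years")
    if (
        not isinstance(years, (list, tuple))
        or len(years) != 2
        or years[1] - years[0] + 1 < 2
    ):
        errors.append("simulation.years must be [first, last] spanning >= 2 years")
    for key in ("cloud_fraction", "water_fraction"):
        if not 0 <= sim[key] <= 1:
            errors.append(f"simulation.{key} must be in [0, 1]")
    if sim["noise_sd"] < 0:
        errors.append("simulation.noise_sd must be >= 0")
    try:
        analysis = AnalysisConfig.from_dict(cfg.get("analysis", {}))
        errors.extend(analysis.validate())
    except (TypeError, ValueError) as exc:
        errors.append(f"analysis section: {exc}")
    return errors


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_model(cfg: dict) -> BACIModel:
    sim = {**DEFAULT_SIMULATION, **cfg.get("simulation", {})}
    analysis = AnalysisConfig.from_dict(cfg.get("analysis", {}))
    return BACIModel.from_simulation(
        n_states=sim["n_states"],
        n_tr=sim["n_tr"],
        n_wls=sim["n_wls"],
        seed=int(cfg.get("seed", 0)),
        scene_pixels=sim["scene_pixels"],
        years=tuple(sim["years"]),
        obs_per_year=sim["obs_per_year"],
        cloud_fraction=sim["cloud_fraction"],
        water_fraction=sim["water_fraction"],
        noise_sd=sim["noise_sd"],
        config=analysis,
    )


def run_pipeline(config_path: str | Path, output_dir: str | Path) -> RunManifest:
    """Execute the full pipeline for a config file.

    Writes the PA table (CSV + GeoJSON), matched pairs, per-PA composition
    summaries, matched-pair comparisons and ternary exports for both epoch
    modes, a plain-text summary, and ``manifest.json``. Deterministic: the
    CSV outputs of two runs of the same config are byte-identical.
    """
    started = time.time()
    config_path = Path(config_path)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    problems = validate_config(config_path)
    if problems:
        raise StageError("validate", ValueError("; ".join(problems)))
    cfg = load_config(config_path)
    outputs: Dict[str, str] = {}

    def save_csv(name: str, frame) -> None:
        path = output_dir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        outputs[name] = str(path)

    try:
        model = build_model(cfg)
    except Exception as exc:
        raise StageError("simulate", exc)

    try:
        model.pa_table.write(
            output_dir / "pa_table.csv", output_dir / "pa_table.geojson"
        )
        outputs["pa_table.csv"] = str(output_dir / "pa_table.csv")
        outputs["pa_table.geojson"] = str(output_dir / "pa_table.geojson")
        results = model.fit()
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fit", exc)

    try:
        save_csv("matched_pairs.csv", results.pairs_frame)
        import pandas as pd

        save_csv(
            "unmatched_trs.csv", pd.DataFrame({"tr_id": results.unmatched_tr_ids})
        )
        save_csv("compositions.csv", results.compositions_frame)
        for mode, tag in (("after-only", "after_only"), ("before-after", "before_after")):
            save_csv(f"comparisons_{tag}.csv", results.comparisons_frame(mode))
            save_csv(f"ternary_{tag}.csv", results.ternary_frame(mode))
        (output_dir / "summary.txt").write_text(results.summary() + "\n")
        outputs["summary.txt"] = str(output_dir / "summary.txt")
    except Exception as exc:
        raise StageError("report", exc)

    manifest = RunManifest(
        config_hash=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        seed=int(cfg.get("seed", 0)),
        version=__version__,
        config_path=str(config_path),
        output_dir=str(output_dir),
        outputs=outputs,
        started=started,
        finished=time.time(),
    )
    (output_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def demo_config_path() -> Path:
    """Bundled demo configuration (2 states, 3 TRs, 6 WLSs, seed 42)."""
    return Path(__file__).parent / "data" / "demo.yaml"


# ---------------------------------------------------------------------------
# Stage-by-stage scene directory format for the standalone CLI commands
# ---------------------------------------------------------------------------

def save_scene(
    directory: str | Path,
    stack: ReflectanceStack,
    declaration_year: int,
    pa_mask: Optional[np.ndarray] = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"times": stack.times.tolist(), "declaration_year": declaration_year}
    (directory / "scene.json").write_text(json.dumps(meta))
    for name, arr in stack.bands.items():
        write_raster(directory / f"band_{name}.tif", arr.astype(np.float32), stack.grid)
    write_raster(directory / "qa.tif", stack.qa, stack.grid)
    if pa_mask is not None:
        write_raster(directory / "pa_mask.tif", pa_mask.astype(np.uint8), stack.grid)


def load_scene(directory: str | Path) -> tuple[ReflectanceStack, int, Optional[np.ndarray]]:
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    bands = {}
    grid: Optional[SceneGrid] = None
    for name in ("blue", "red", "nir", "swir1"):
        arr, grid = read_raster(directory / f"band_{name}.tif")
        bands[name] = arr.astype(float)
    qa, _ = read_raster(directory / "qa.tif")
    pa_mask = None
    if (directory / "pa_mask.tif").exists():
        m, _ = read_raster(directory / "pa_mask.tif")
        pa_mask = m.astype(bool)
    stack = ReflectanceStack(
        grid=grid, times=np.asarray(meta["times"]), bands=bands, qa=qa
    )
    return stack, int(meta["declaration_year"]), pa_mask
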