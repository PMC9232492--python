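"""End-to-end scenario runner: synth → preprocess → fit → compare.

One YAML config drives the whole run. For every named condition the runner
generates (or ingests) per-cell traces, preprocesses and averages them, fits
the condition mean on a shared simulation grid, and writes fit summaries,
condition deltas relative to a reference condition, a recovery-curve figure
and a run manifest. Deterministic given the config's seeds: the simulation
grid is simulated once and scored against every condition.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ._version import __version__
from .config import (
    build_grid,
    build_noise_spec,
    build_sim_config,
    load_config,
)
from .errors import ConfigError, InputError
from .fit import FitSummary, compare_conditions, score_grid, select_best, simulate_grid
from .models import mix_seed
from .preprocess import (
    DEFAULT_REFERENCE_WINDOW,
    average_curves,
    curves_to_frame,
    mean_curve_to_frame,
    prebleach_level_summary,
    preprocess_trace,
    read_traces_csv,
)
from .synth import generate_cells, make_condition_model

__all__ = ["RunManifest", "run_scenario"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of one scenario run: config hash, seeds, versions, outputs."""

    config_hash: str
    seeds: dict[str, int]
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def _hash_config(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_scenario(config, out_dir) -> RunManifest:
    """Run a full scenario described by a YAML path or config dict.

    The scenario section must name at least one condition; with two or more,
    percent changes of every fitted parameter are reported relative to the
    reference condition (the first one unless ``scenario.reference`` is set).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    scenario = dict(cfg.get("scenario", {}))
    conditions = list(scenario.get("conditions", []))
    if not conditions:
        raise ConfigError("scenario must name at least one condition")
    reference = scenario.get("reference", conditions[0])
    if reference not in conditions:
        raise ConfigError(f"reference condition {reference!r} not in scenario")
    n_cells = int(scenario.get("n_cells", 10))
    # Synthetic cells emulate real nuclei, which hold ~1e5 polymerase copies;
    # their particle budget is therefore set independently of the fit grid's.
    cell_particles = int(scenario.get("cell_particles", 100_000))
    n_best = int(cfg.get("fit", {}).get("n_best", 20))
    ref_window = tuple(cfg.get("preprocess", {}).get("reference_window", DEFAULT_REFERENCE_WINDOW))

    sim = build_sim_config(cfg)
    from dataclasses import replace as _replace

    cell_sim = _replace(sim, n_particles=cell_particles)
    noise = build_noise_spec(cfg)
    grid = build_grid(cfg)

    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)

    manifest = RunManifest(
        config_hash=_hash_config(cfg),
        seeds={"simulation": sim.seed, "noise": noise.seed},
        version=__version__,
        started=time.time(),
    )

    logger.info("stage synth+preprocess: %d conditions × %d cells", len(conditions), n_cells)
    mean_curves = {}
    levels = {}
    for ci, label in enumerate(conditions):
        traces_path = scenario.get("traces")
        if traces_path:
            traces = [
                t for t in read_traces_csv(traces_path) if t.condition_label == label
            ]
            if not traces:
                raise InputError(f"no traces for condition {label!r} in {traces_path}")
        else:
            model = make_condition_model(label)
            cond_noise = type(noise)(
                frame_noise_sd=noise.frame_noise_sd,
                cell_scale_sd=noise.cell_scale_sd,
                background_level=noise.background_level,
                base_level=noise.base_level,
                seed=mix_seed(noise.seed, ci),
            )
            traces = generate_cells(model, cond_noise, n_cells, cell_sim, condition_label=label)
        curves = [preprocess_trace(t, ref_window) for t in traces]
        mean_curves[label] = average_curves(curves)
        levels[label] = prebleach_level_summary(curves)
        slug = label.replace(" ", "_").replace("/", "-")
        cpath = out / "curves" / f"{slug}.csv"
        curves_to_frame(curves).to_csv(cpath, index=False, float_format="%.10g")
        mpath = out / "curves" / f"{slug}_mean.csv"
        mean_curve_to_frame(mean_curves[label]).to_csv(mpath, index=False, float_format="%.10g")
        manifest.outputs[f"curves/{label}"] = str(cpath)
        manifest.outputs[f"mean_curve/{label}"] = str(mpath)

    logger.info("stage fit: simulating grid of %d points", grid.size)
    grid_curves = simulate_grid(grid, sim)
    summaries: dict[str, FitSummary] = {}
    for label in conditions:
        scored = score_grid(grid_curves, mean_curves[label])
        summaries[label] = select_best(scored, n_best=n_best, condition_label=label)
        slug = label.replace(" ", "_").replace("/", "-")
        spath = out / "fits" / f"{slug}_summary.json"
        summaries[label].to_json(spath)
        manifest.outputs[f"fit/{label}"] = str(spath)

    report = {
        "conditions": conditions,
        "reference": reference,
        "prebleach_levels": {
            k: {"mean": v[0], "sd": v[1]} for k, v in levels.items()
        },
        "fits": {k: v.to_dict() for k, v in summaries.items()},
    }
    ref_level = levels[reference][0]
    report["relative_levels"] = {
        k: v[0] / ref_level for k, v in levels.items()
    }
    if len(conditions) >= 2:
        report["deltas_vs_reference"] = {
            label: compare_conditions(summaries[reference], summaries[label])
            for label in conditions
            if label != reference
        }
    else:
        logger.info("single-condition scenario: comparison stage skipped")
        report["deltas_vs_reference"] = None

    rpath = out / "report.json"
    with open(rpath, "w") as fh:
        json.dump(report, fh, indent=2)
    manifest.outputs["report"] = str(rpath)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label in conditions:
        mc = mean_curves[label]
        ax.plot(mc.times, mc.rfi_mean, label=label, lw=1)
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("RFI")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fpath = out / "curves.png"
    fig.savefig(fpath, dpi=120)
    plt.close(fig)
    manifest.outputs["figure"] = str(fpath)

    manifest.finished = time.time()
    mpath = out / "manifest.json"
    manifest.to_json(mpath)
    return manifest
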