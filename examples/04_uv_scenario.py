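"""End-to-end UV-damage scenario: synth → preprocess → fit → compare.

Runs the pipeline for the unperturbed and the 1-2 h post-UV conditions and
prints the recovered condition deltas. Outputs (per-cell curves, mean curves,
fit summaries, report.json, a figure and a run manifest) land in
./scenario_out/.
"""

import json
from pathlib import Path

from polfrap import run_scenario

config = {
    "simulation": {"n_particles": 10_000, "dt": 0.1, "seed": 1},
    "noise": {"seed": 1},
    "grid": {
        "f_prom": [0.1125, 0.225, 0.45],
        "f_elong": [0.30, 0.35],
        "t_prom": [30.0],
        "t_elong": [1380.0, 1725.0],
        "seed_offsets": [0, 1, 2, 3],
    },
    # best-8 of a 12-model demo grid: the summary then covers the top two
    # grid points (4 replicate seeds each) instead of spreading over half
    # the grid
    "fit": {"n_best": 8},
    "scenario": {
        "conditions": ["0 J", "4 J 1-2 h"],
        "reference": "0 J",
        "n_cells": 6,
        "cell_particles": 50_000,
    },
}

out = Path("scenario_out")
manifest = run_scenario(config, out)
report = json.loads((out / "report.json").read_text())

deltas = report["deltas_vs_reference"]["4 J 1-2 h"]
levels = report["relative_levels"]
print(f"promoter-bound fraction change : {deltas['f_prom']:+.1f} %  (generator truth: -75 %)")
print(f"elongating fraction change     : {deltas['f_elong']:+.1f} %")
print(f"relative Pol II level (1-2 h)  : {levels['4 J 1-2 h']:.2f}   (generator truth: 0.75)")
print(f"\nfull report: {out / 'report.json'}")
print(f"run manifest (seeds, hashes, outputs): {out / 'manifest.json'}")
print("\nThe negative promoter-bound delta together with the reduced pre-bleach level")
print("is the in-trans signature: promoter-bound polymerase is degraded, not stalled.")
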