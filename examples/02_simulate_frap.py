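"""Simulate strip-FRAP curves for unperturbed and UV-damaged Pol II kinetics.

Runs the Monte Carlo engine for the built-in condition models and prints the
recovery at a few landmark times. The early recovery (< 50 s) is dominated by
free and promoter-bound polymerase; the late slope (> 100 s) reflects the
slow exchange of elongating polymerase.
"""

import numpy as np

from polfrap import SimulationConfig, make_condition_model, simulate_frap

sim = SimulationConfig(n_particles=20_000, dt=0.1, seed=7)

print(f"{'condition':>12} | {'RFI @ 0 s':>9} {'@ 10 s':>7} {'@ 50 s':>7} {'@ 120 s':>8} {'@ 240 s':>8}")
curves = {}
for label in ("0 J", "4 J 0-1 h", "4 J 1-2 h"):
    curve = simulate_frap(make_condition_model(label), sim)
    curves[label] = curve
    vals = [curve.rfi[np.searchsorted(curve.times, t)] for t in (0, 10, 50, 120, 240)]
    print(f"{label:>12} | " + " ".join(f"{v:7.1f}" for v in vals) + f"  (seed {curve.seed})")

base, trans = curves["0 J"], curves["4 J 1-2 h"]
print("\nThe '4 J 0-1 h' curve recovers more slowly late (longer elongating residence,")
print("slightly larger elongating fraction). The '4 J 1-2 h' curve recovers *faster*")
print(f"early (at 10 s: {trans.rfi[np.searchsorted(trans.times, 10)]:.0f} vs "
      f"{base.rfi[np.searchsorted(base.times, 10)]:.0f} RFI) because promoter-bound")
print("polymerase has been degraded and its share moved to the free pool.")
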