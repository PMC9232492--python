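"""Recover kinetic parameters from a noisy synthetic cohort by grid search.

Generates a 6-cell cohort from the unperturbed condition model, fits the
condition mean against a small simulation grid, and prints the mean ± SD of
the best-fitting simulations next to the generating truth. A desk-sized run:
the grid is deliberately coarse (see scripts/acceptance.py for the full one).
"""

from dataclasses import replace

from polfrap import (
    NoiseSpec,
    ParameterGrid,
    SimulationConfig,
    average_curves,
    generate_cells,
    grid_fit,
    make_condition_model,
    preprocess_trace,
    select_best,
)

truth = make_condition_model("0 J")
fit_sim = SimulationConfig(n_particles=10_000, dt=0.1, seed=1)
cell_sim = replace(fit_sim, n_particles=50_000)

cells = generate_cells(truth, NoiseSpec(seed=11), 6, cell_sim, condition_label="0 J")
target = average_curves([preprocess_trace(t) for t in cells])

grid = ParameterGrid(
    f_prom=(0.1125, 0.225, 0.45),
    f_elong=(0.25, 0.30, 0.35),
    t_prom=(15.0, 30.0, 60.0),
    t_elong=(18 * 60.0, 23 * 60.0, 28.75 * 60.0),
    seed_offsets=(0, 1, 2, 3),
)
print(f"fitting {grid.size} simulations ...")
scored = grid_fit(target, grid, fit_sim)
summary = select_best(scored, n_best=20, condition_label="0 J")

print(f"{'parameter':>10} | {'truth':>8} | recovered (mean ± SD of 20 best)")
for name, true_value in [
    ("f_prom", truth.f_prom), ("f_elong", truth.f_elong),
    ("t_prom", truth.t_prom), ("t_elong", truth.t_elong),
]:
    print(f"{name:>10} | {true_value:8.3f} | {summary.means[name]:8.3f} ± {summary.sds[name]:.3f}")
print(f"best score {summary.scores[0]:.0f}, worst of the kept 20: {summary.scores[-1]:.0f}")
print("\nFractions and the promoter residence time pin down sharply; the elongating")
print("residence time is intrinsically soft on a 4-minute trace, which the SD reflects.")
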