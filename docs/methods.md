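# Methods

## The measurement and the model

Strip-FRAP measures the mobility of a fluorescently tagged nuclear protein:
a narrow strip spanning the nucleus is imaged at a fixed frame interval, the
fluorophores inside the strip are bleached by a single high-power frame, and
the return of fluorescence into the strip mixes two processes — diffusion of
unbleached molecules into the strip, and exchange of chromatin-bound
molecules. For RNA polymerase II (GFP-tagged RPB1) the recovery curve carries
kinetic signatures of the transcription cycle: freely diffusing polymerase
recovers within seconds, initiating/promoter-paused polymerase exchanges on a
sub-minute timescale, and productively elongating polymerase stays bound for
tens of minutes and dominates the late, slowly rising part of the curve.

`polfrap` models this with a three-state kinetic scheme:

* **free** — isotropic Brownian motion with diffusion coefficient `D`
  (default 2.0 µm²/s), confined to an ellipsoidal nucleus;
* **promoter-bound** — immobile, exponential dwell with mean `t_prom`
  (baseline 30 s; the regime constraint is "under a minute");
* **elongating** — immobile, exponential dwell with mean `t_elong`
  (baseline 23 min; the regime constraint is "over 20 min"). A fixed-duration
  dwell (processive elongation) is available via `fixed_elong_dwell`.

Binding sites are assumed uniformly distributed, so a free molecule binds
from any position with pseudo-first-order rates

    k_on,p = f_prom / (f_free · t_prom),    k_on,e = f_elong / (f_free · t_elong)

which make the configured fractions `(f_free, f_prom, f_elong)` the exact
steady state, and a molecule resumes diffusing where it unbound. This is the
minimal scheme consistent with specifying fraction sizes and mean residence
times only; it ignores photophysics, anomalous diffusion, spatially
heterogeneous binding-site density, and movement of bound complexes
(elongation translocation is ~nm/s, irrelevant on the 1.5 µm strip scale).

## Acquisition and geometry defaults

| parameter | default | note |
|---|---|---|
| frame interval | 0.4 s | confocal strip protocol |
| pre-bleach frames | 25 | reference window: pre-bleach frames 10–20 (0-based, inclusive) |
| bleach | 1 frame, depth 0.85 | depth = P(darkening) for an in-strip fluorophore |
| recovery | 240 s | protocol monitors 3–4 min |
| nucleus | ellipsoid, semi-axes 10 × 5 × 2.5 µm | flat adherent-cell nucleus |
| strip | slab \|x\| ≤ 0.75 µm through the centre | spans the nucleus in y, z |
| diffusion substep `dt` | 0.02 s | RMS substep 0.28 µm ≪ strip width |

The physical mapping of the imaged pixel strip to µm is not observable from
the trace data, so nucleus and strip dimensions are explicit, configurable
stand-ins. `D` and `bleach_depth` are *not* fitted; `estimate_bleach_depth`
calibrates the depth from the first post-bleach RFI reading
(`depth ≈ 1 − RFI(0)/100`).

## Preprocessing

Per-frame background correction subtracts the out-of-strip signal; negative
corrected values are clipped to 0 to keep intensities physical (behaviour at
this edge is a package convention). The mean corrected intensity over
pre-bleach frames 10–20 defines the pre-bleach FI — kept as a total-protein
proxy — and the trace is rescaled so that this mean is exactly 100 (RFI).
The time axis is re-zeroed at the bleach frame, so pre-bleach frames carry
negative times and measured and simulated curves align on one grid. Whether
the original protocol counted frames 10–20 from 0 or 1 is not decidable from
the protocol text; this package uses 0-based indices into the pre-bleach
block, configurable via `reference_window`. Curves of unequal length within
a condition are truncated to the shortest, with a logged warning.

## Monte Carlo engine

The production kernel is particle-major: each particle carries its own
counter-seeded RNG stream and is simulated over the whole acquisition before
the next one starts. Design choices that matter for fitting accuracy:

* **Exact dwell sampling.** Waiting and dwell times are drawn from their
  exponential distributions and applied on the substep grid (event times
  quantized to at most one substep, the same resolution a per-substep
  Bernoulli scheme would give, without its first-order rate error).
* **Competing-exponential binding with fixed draw consumption.** Each free
  period consumes exactly two Exp(1) draws, scaled by the per-channel mean
  waiting times. A particle's trajectory is therefore a smooth function of
  each rate: re-simulating with the same seed and a neighbouring grid model
  perturbs trajectories instead of redrawing them (common random numbers),
  so score differences across the grid reflect the parameters, not Monte
  Carlo jitter.
* **Stratified initialization.** State counts are apportioned exactly
  (largest remainder); initial x-positions are stratified quantiles of the
  equilibrium marginal, which pins each pool's initial in-strip share at its
  expectation.
* **Metropolis boundary.** A substep that would exit the ellipsoid is
  rejected and the particle stays put. The stationary density of this rule
  is exactly uniform at any step size (symmetric proposal, uniform target);
  true specular reflection is recovered as `dt → 0`. The alternative
  (resample until inside) has a stationary density proportional to the
  in-domain Gaussian mass, which measurably depletes the boundary region at
  coarse substeps.
* **Fractional bleach (default).** The bleach multiplies each in-strip
  particle's fluorescence weight by `1 − depth` instead of darkening it with
  probability `depth`; the expectation is identical and the binomial bleach
  noise vanishes. `bleach_mode="bernoulli"` restores hard darkening.
* **Deficit readout (default).** The in-strip fluorescence decomposes as
  `F(t) = N_strip(t) − depth · N^b_strip(t)` with `N^b` the bleached subset.
  Because binding is position-independent and the dynamics start in
  equilibrium, `E[N_strip] = N̄` is known analytically, and the estimator
  `RFI(t) = 100 · (N̄ − depth · N^b_strip(t)) / N̄` (a Rao-Blackwellization)
  only requires simulating particles that start inside the strip. It is
  unbiased for the expected curve, starts at zero variance (the bleached
  subset's initial condition is known), is free of the unbleached pool's
  equilibrium occupancy fluctuations — the dominant noise term of the naive
  readout — and is ~8× faster. `estimator="ensemble"` forces the direct
  full-ensemble readout, which is also what `simulate_occupancy` and the
  granular `init/step/bleach/readout` operations expose.

## Grid fitting

The objective is unweighted SSE over post-bleach frames (both curves are
pinned at 100 before the bleach, so pre-bleach frames carry no information).
One simulation is run per grid point × replicate seed; the scored list is
sorted ascending with ties broken by enumeration order, and the fit summary
is the mean ± SD of each parameter over the 20 best-fitting simulations.
`D` and `bleach_depth` are held fixed; percent changes between conditions
are computed from best-20 parameter means.

Replicate seeds are shared across grid points (common random numbers), and
by default the replicate curves of a grid point are averaged into its
ensemble estimate before scoring (`score_grid(..., aggregate="mean_curve")`)
— the simulation-side counterpart of the cell-averaged measured curve. Each
of the grid point's replicate simulations then carries the SSE of that mean
curve, so with `R` replicates the 20 best-fitting simulations are the
replicates of the top `20/R` grid points. This matters for the weakly
identified direction: the expectation of a single-run SSE is
Σ bias² + Σ Var(simulation) + Σ Var(target), and for `t_elong` the bias²
separation between neighbouring grid values (tens of SSE units on a 4-minute
trace) is far below the single-run variance term, so per-run scoring selects
by Monte Carlo noise and the best-20 mean collapses toward the grid centroid.
Averaging divides the simulation-variance term by `R` and restores selection
by misfit. Scoring every run on its own curve remains available
(`aggregate="per_replicate"`); the `score` operation itself is always the
plain SSE.

Even with averaged scoring, the recovered `t_elong` is grid-quantized: the
summary mean lands on the average of the handful of top-ranked grid values,
and which neighbour joins the winner is decided by margins of a few tens of
SSE units against cohort-level noise of the same size (dominated by the
pre-bleach normalization error of a 10-cell cohort, a single multiplicative
degree of freedom per cell). Between-condition percent changes of `t_elong`
therefore have a discrete, seed-dependent sampling distribution spanning
roughly ±10 percentage points under cohort resampling; the fraction sizes
and the promoter residence time do not share this fragility (their grid
separations are two orders of magnitude above the noise).

`t_elong` is intrinsically at the edge of identifiability for a 240 s trace:
models with `t_elong` of 23 vs 29 min differ by under 1 RFI unit in the tail,
so the recovered mean carries a grid-quantized SD of several minutes, and the
between-condition percent change is a stochastic quantity with a spread of
several percentage points under cohort resampling.

## Synthetic data

The generator inverts the preprocessing chain: a noise-free ensemble curve
(simulated at 1e5 particles — the order of the real RPB1 copy number per
nucleus, so particle shot noise is negligible next to measurement noise) is
scaled into raw units by a per-cell pre-bleach level
`base_level × lognormal(σ = cell_scale_sd) × level_scale`, a constant
out-of-strip background (10% of the mean signal) is added, and per-frame
Gaussian measurement noise of 2 RFI units is applied. Condition models:

| label | change vs baseline |
|---|---|
| `0 J` | baseline: f = (0.25, 0.45, 0.30), t_prom = 30 s, t_elong = 23 min |
| `4 J 0-1 h` | in-cis block: t_elong × 1.25, f_elong + 0.05 (from f_free) |
| `4 J 1-2 h` | plus in-trans loss: f_prom × 0.25 (released share → f_free), total level × 0.75 |
| `4 J 20-21 h` | recovered: baseline |
| `16 J 0-1 h` | full in-cis effect, no extra in-trans effect (the trans loss does not scale with dose) |

The exact baseline fractions are package conventions constrained by the
regime bounds (t_prom < 1 min, t_elong > 20 min, +25% in-cis, −75% in-trans);
they are not measured values. What the generator does **not** emulate: shot
noise that scales with intensity, bleaching during acquisition, cell motion,
focus drift, heterogeneous binding-site geography, or local (sub-nuclear)
damage patterns. Passing recovery tests therefore demonstrates that the
inference chain is self-consistent under the stated noise model, not that it
is robust to every artefact of real microscopy data.

## Problem sizes used by the test suite and the acceptance script

Recovery runs use 10 cells per condition, cells at 1e5 particles, fitted
simulations at 4×10⁴ particles with `dt = 0.4 s` (one substep per frame —
the same particle-substep budget as 10⁴ particles at `dt = 0.1 s`, allocated
toward particle count, which is where selection accuracy gains; generator
and fitter share the integrator, so discretization bias cancels in the
comparison), a 162-point grid (6 `t_elong` × 3 values per other parameter)
with 10 replicate seeds per point, and best-20 selection. Physics oracles
run at their own scales (up to 2×10⁵ particles at `dt = 0.02 s`). The
library defaults remain `dt = 0.02 s` and single replicates.

## Numerical edge cases

* `f_free = 0` (fully bound pool): binding rates are defined as 0; bleached
  bound particles never move and the curve stays at its post-bleach value.
* Degenerate traces (non-positive pre-bleach reference) raise
  `DegenerateTraceError` rather than producing unnormalizable output.
* Score ties are broken by grid enumeration order; duplicated grid points
  collapse to identical scores and leave best-n means unchanged.
* Seeds derived anywhere in the package are folded through a splitmix-style
  mixer and stay below 2³¹.
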