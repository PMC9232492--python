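"""Synthetic ground-truth conditions and noisy per-cell strip-FRAP traces.

The condition models emulate the kinetic regimes of a UV-damage time course
on RNA polymerase II:

* ``"0 J"`` — unperturbed: a promoter-bound pool with sub-minute residence, an
  elongating pool bound for tens of minutes.
* ``"4 J 0-1 h"`` — within the first hour after UV, elongating polymerase
  stalls on transcription-blocking lesions in cis: the elongating residence
  time is prolonged by 25% and the elongating fraction grows slightly at the
  expense of the free pool.
* ``"4 J 1-2 h"`` — between one and two hours after UV the promoter-bound
  fraction is depleted in trans (degradation of promoter-bound polymerase):
  the promoter-bound fraction falls to 25% of baseline, the released share
  moves to the free pool, and total protein level drops to 75%.
* ``"4 J 20-21 h"`` — recovery: back to baseline kinetics.
* ``"16 J 0-1 h"`` — high damage load: the full 25% in-cis prolongation with
  no additional in-trans effect (the trans loss does not scale with dose).

The exact baseline fractions are package conventions chosen to satisfy the
regime's qualitative bounds (promoter residence < 1 min, elongating residence
> 20 min); they are not measured values.

Noisy traces are generated by inverting the preprocessing chain: a noise-free
ensemble curve from the Monte Carlo engine is scaled to raw units through a
per-cell lognormal expression level, a constant out-of-strip background is
added, and per-frame Gaussian measurement noise is applied.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .models import (
    ConditionSpec,
    KineticModel,
    NoiseSpec,
    SimulationConfig,
    mix_seed,
)
from .preprocess import RawTrace
from .simulate import simulate_frap

__all__ = [
    "CONDITION_LABELS",
    "make_condition_model",
    "make_condition_spec",
    "generate_cells",
]

_BASELINE = KineticModel(
    f_free=0.25,
    f_prom=0.45,
    f_elong=0.30,
    t_prom=30.0,
    t_elong=23.0 * 60.0,
    level_scale=1.0,
)

#: In-cis effect: prolongation of the elongating residence time after UV.
CIS_T_ELONG_FACTOR = 1.25
#: In-cis effect: share of the free pool shifted into elongation.
CIS_F_ELONG_SHIFT = 0.05
#: In-trans effect: surviving share of the promoter-bound fraction.
TRANS_F_PROM_FACTOR = 0.25
#: In-trans effect: total protein level relative to baseline.
TRANS_LEVEL_SCALE = 0.75


def _cis_model(base: KineticModel) -> KineticModel:
    return KineticModel(
        f_free=base.f_free - CIS_F_ELONG_SHIFT,
        f_prom=base.f_prom,
        f_elong=base.f_elong + CIS_F_ELONG_SHIFT,
        t_prom=base.t_prom,
        t_elong=base.t_elong * CIS_T_ELONG_FACTOR,
        D=base.D,
        level_scale=base.level_scale,
    )


def _trans_model(base: KineticModel) -> KineticModel:
    cis = _cis_model(base)
    new_f_prom = cis.f_prom * TRANS_F_PROM_FACTOR
    return KineticModel(
        f_free=cis.f_free + (cis.f_prom - new_f_prom),
        f_prom=new_f_prom,
        f_elong=cis.f_elong,
        t_prom=cis.t_prom,
        t_elong=cis.t_elong,
        D=cis.D,
        level_scale=TRANS_LEVEL_SCALE,
    )


_CONDITIONS: dict[str, tuple[KineticModel, float, tuple[float, float]]] = {
    "0 J": (_BASELINE, 0.0, (0.0, 0.0)),
    "4 J 0-1 h": (_cis_model(_BASELINE), 4.0, (0.0, 1.0)),
    "4 J 1-2 h": (_trans_model(_BASELINE), 4.0, (1.0, 2.0)),
    "4 J 20-21 h": (_BASELINE, 4.0, (20.0, 21.0)),
    "16 J 0-1 h": (_cis_model(_BASELINE), 16.0, (0.0, 1.0)),
}

CONDITION_LABELS = tuple(_CONDITIONS)


def make_condition_model(label: str) -> KineticModel:
    """Ground-truth kinetic model for a named experimental condition."""
    try:
        return _CONDITIONS[label][0]
    except KeyError:
        raise InputError(
            f"unknown condition {label!r}; known labels: {list(_CONDITIONS)}"
        ) from None


def make_condition_spec(label: str) -> ConditionSpec:
    model, dose, window = _CONDITIONS[label] if label in _CONDITIONS else (None, None, None)
    if model is None:
        raise InputError(
            f"unknown condition {label!r}; known labels: {list(_CONDITIONS)}"
        )
    return ConditionSpec(label=label, uv_dose=dose, time_window=window, model=model)


def generate_cells(
    model: KineticModel,
    noise: NoiseSpec,
    n_cells: int,
    sim: SimulationConfig,
    condition_label: str = "",
) -> list[RawTrace]:
    """Generate noisy per-cell raw traces from a ground-truth model.

    Each cell gets a distinct simulation seed, a lognormal expression-level
    factor (sigma ``noise.cell_scale_sd``), raw units via a cell pre-bleach
    level of ``base_level × scale × model.level_scale``, a constant background
    and per-frame Gaussian noise of ``frame_noise_sd`` RFI units. The traces
    round-trip exactly through preprocessing when all noise terms are zero.
    """
    if n_cells < 1:
        raise InputError("n_cells must be at least 1")
    traces = []
    for i in range(n_cells):
        cell_seed = mix_seed(noise.seed, i)
        curve = simulate_frap(model, sim, seed=cell_seed)
        rng = np.random.default_rng(mix_seed(noise.seed, i, 1))
        scale = float(rng.lognormal(mean=0.0, sigma=noise.cell_scale_sd)) if noise.cell_scale_sd > 0 else 1.0
        level = noise.base_level * scale * model.level_scale
        raw = curve.rfi / 100.0 * level + noise.background_level
        if noise.frame_noise_sd > 0:
            raw = raw + rng.normal(0.0, noise.frame_noise_sd * level / 100.0, size=raw.size)
        raw = np.clip(raw, 0.0, None)
        n_pre = sim.acquisition.n_prebleach_frames
        times = curve.times - curve.times[0]  # raw traces start at t = 0
        traces.append(
            RawTrace(
                cell_id=f"cell_{i:03d}",
                times=times,
                strip_intensity=raw,
                background_intensity=np.full(raw.size, noise.background_level),
                bleach_frame_index=n_pre,
                condition_label=condition_label,
            )
        )
    return traces
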