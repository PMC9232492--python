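"""Domain types for the strip-FRAP kinetic model and acquisition protocol.

The kinetic picture is a three-state model of nuclear RNA polymerase II:
a freely diffusing pool, a short-lived promoter-bound pool (initiating plus
promoter-proximally paused polymerase), and a long-lived elongating pool.
Fraction sizes are steady-state shares of the whole pool; residence times are
mean chromatin-bound dwell times (exponential dwell unless the processive
fixed-dwell option is enabled in the simulator).

Acquisition mirrors a confocal strip-FRAP protocol: a narrow strip spanning
the nucleus is imaged at a fixed frame interval, a number of pre-bleach frames
is recorded, fluorescence in the strip is bleached for one frame, and recovery
is monitored for a few minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigError, ModelError

__all__ = [
    "KineticModel",
    "AcquisitionConfig",
    "GeometryConfig",
    "SimulationConfig",
    "NoiseSpec",
    "ConditionSpec",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class KineticModel:
    """Three-state kinetic model of a nuclear protein pool.

    Parameters
    ----------
    f_free, f_prom, f_elong
        Steady-state fractions of freely diffusing, promoter-bound and
        elongating molecules. Must sum to 1.
    t_prom, t_elong
        Mean chromatin residence times of the two bound states, in seconds.
    D
        Diffusion coefficient of the free state, µm²/s.
    level_scale
        Total-abundance multiplier relative to the unperturbed condition
        (dimensionless); affects raw intensity levels only, never the shape
        of a normalized recovery curve.
    """

    f_free: float
    f_prom: float
    f_elong: float
    t_prom: float = 30.0
    t_elong: float = 23.0 * 60.0
    D: float = 2.0
    level_scale: float = 1.0

    def __post_init__(self) -> None:
        fractions = (self.f_free, self.f_prom, self.f_elong)
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise ModelError(f"fractions must lie in [0, 1], got {fractions}")
        if abs(sum(fractions) - 1.0) > _FRACTION_TOL:
            raise ModelError(
                f"fractions must sum to 1 within {_FRACTION_TOL}, got {sum(fractions)!r}"
            )
        if self.t_prom <= 0 or self.t_elong <= 0:
            raise ModelError("residence times must be positive")
        if self.D <= 0:
            raise ModelError("diffusion coefficient must be positive")
        if self.level_scale <= 0:
            raise ModelError("level_scale must be positive")

    @property
    def k_off_prom(self) -> float:
        """Promoter-state unbinding rate, 1/s."""
        return 1.0 / self.t_prom

    @property
    def k_off_elong(self) -> float:
        """Elongating-state unbinding rate, 1/s."""
        return 1.0 / self.t_elong

    @property
    def k_on_prom(self) -> float:
        """Pseudo-first-order promoter binding rate making ``f_prom`` the steady state."""
        if self.f_free == 0.0:
            return 0.0
        return self.f_prom / (self.f_free * self.t_prom)

    @property
    def k_on_elong(self) -> float:
        """Pseudo-first-order elongation-entry rate making ``f_elong`` the steady state."""
        if self.f_free == 0.0:
            return 0.0
        return self.f_elong / (self.f_free * self.t_elong)

    def with_level_scale(self, level_scale: float) -> "KineticModel":
        return replace(self, level_scale=level_scale)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Strip-FRAP acquisition protocol.

    Defaults follow a confocal protocol imaging every 0.4 s with 25 pre-bleach
    frames and a single-frame bleach pulse, monitoring recovery for 4 min.
    """

    frame_interval: float = 0.4
    n_prebleach_frames: int = 25
    recovery_duration: float = 240.0
    bleach_depth: float = 0.85

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.n_prebleach_frames < 1:
            raise ConfigError("need at least one pre-bleach frame")
        if self.recovery_duration < self.frame_interval:
            raise ConfigError("recovery_duration must cover at least one frame")
        if not (0.0 < self.bleach_depth <= 1.0):
            raise ConfigError("bleach_depth must lie in (0, 1]")

    @property
    def n_recovery_frames(self) -> int:
        return int(round(self.recovery_duration / self.frame_interval))

    @property
    def n_frames(self) -> int:
        """Total frames: pre-bleach block, one bleach frame, recovery block."""
        return self.n_prebleach_frames + 1 + self.n_recovery_frames

    def frame_times(self):
        """Frame time stamps in seconds, re-zeroed at the bleach frame."""
        import numpy as np

        idx = np.arange(self.n_frames)
        return (idx - self.n_prebleach_frames) * self.frame_interval


@dataclass(frozen=True)
class GeometryConfig:
    """Nucleus and bleach-strip geometry.

    The nucleus is a 3D ellipsoid with semi-axes ``(a, b, c)`` in µm; the
    default (10, 5, 2.5) approximates a flat fibroblast nucleus. The strip is
    an axis-aligned slab ``|x| <= strip_width / 2`` through the nucleus centre,
    spanning the nucleus in y and z.
    """

    semi_axes: tuple[float, float, float] = (10.0, 5.0, 2.5)
    strip_width: float = 1.5

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes):
            raise ConfigError("ellipsoid semi-axes must be positive")
        if self.strip_width <= 0:
            raise ConfigError("strip width must be positive")
        if self.strip_width >= 2.0 * self.semi_axes[0]:
            raise ConfigError("strip must be narrower than the nucleus")

    @property
    def half_width(self) -> float:
        return 0.5 * self.strip_width

    def strip_volume_fraction(self) -> float:
        """Fraction of the ellipsoid volume inside the strip slab.

        For a slab |x| <= w/2 in an ellipsoid with semi-axis a along x the
        enclosed volume fraction is (3u - u^3) / 2 with u = min(w / (2a), 1).
        """
        u = min(self.half_width / self.semi_axes[0], 1.0)
        return 0.5 * (3.0 * u - u**3)


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo settings: particle count, diffusion substep, seed, geometry."""

    n_particles: int = 10_000
    dt: float = 0.02
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fixed_elong_dwell: bool = False
    bleach_mode: str = "fractional"
    estimator: str = "deficit"

    def __post_init__(self) -> None:
        if self.n_particles < 100:
            raise ConfigError("n_particles must be at least 100")
        fi = self.acquisition.frame_interval
        if not (0.0 < self.dt <= fi):
            raise ConfigError("dt must lie in (0, frame_interval]")
        n_sub = fi / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ConfigError("frame_interval must be an integer multiple of dt")
        if self.bleach_mode not in ("fractional", "bernoulli"):
            raise ConfigError("bleach_mode must be 'fractional' or 'bernoulli'")
        if self.estimator not in ("deficit", "ensemble"):
            raise ConfigError("estimator must be 'deficit' or 'ensemble'")

    @property
    def substeps_per_frame(self) -> int:
        return int(round(self.acquisition.frame_interval / self.dt))


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic per-cell traces.

    ``frame_noise_sd`` is additive per-frame Gaussian noise in RFI units
    (converted to raw units through each cell's pre-bleach level);
    ``cell_scale_sd`` is the sigma of a per-cell multiplicative lognormal
    expression-level factor; ``background_level`` is a constant out-of-strip
    signal in the same arbitrary units as the raw traces.
    """

    frame_noise_sd: float = 2.0
    cell_scale_sd: float = 0.1
    background_level: float = 100.0
    base_level: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_noise_sd < 0 or self.cell_scale_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.background_level < 0:
            raise ConfigError("background_level must be non-negative")
        if self.base_level <= 0:
            raise ConfigError("base_level must be positive")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: label, UV dose, post-UV window, ground truth."""

    label: str
    uv_dose: float
    time_window: tuple[float, float]
    model: KineticModel


def mix_seed(*parts: int) -> int:
    """Deterministically fold several integers into one 31-bit seed.

    splitmix64-style avalanche; keeps derived seeds well below 2**31 so they
    stay valid for every RNG in the stack.
    """
    h = 0x9E3779B97F4A7C15
    for p in parts:
        h ^= (p & 0xFFFFFFFFFFFFFFFF) + 0x9E3779B97F4A7C15 + ((h << 6) & 0xFFFFFFFFFFFFFFFF) + (h >> 2)
        h &= 0xFFFFFFFFFFFFFFFF
        h ^= h >> 30
        h = (h * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
        h ^= h >> 27
    return int(h % (2**31 - 1))


def _isclose(a: float, b: float, tol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=0.0, abs_tol=tol)
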