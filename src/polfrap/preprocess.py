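"""Preprocessing of raw strip-FRAP traces.

Raw per-cell traces (in-strip intensity plus an out-of-strip background
signal) are background-corrected, normalized so the pre-bleach mean is 100
(RFI, relative fluorescence intensity), re-zeroed in time at the bleach
frame, and averaged per condition. The background-corrected pre-bleach
intensity is kept as a proxy for total protein level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateTraceError, InputError

__all__ = [
    "RawTrace",
    "NormalizedCurve",
    "MeanCurve",
    "DEFAULT_REFERENCE_WINDOW",
    "background_correct",
    "normalize_prebleach",
    "preprocess_trace",
    "average_curves",
    "prebleach_level_summary",
    "read_traces_csv",
    "curves_to_frame",
    "mean_curve_to_frame",
]

logger = logging.getLogger(__name__)

#: Pre-bleach frames used as the normalization reference (0-based, inclusive,
#: indices within the pre-bleach block).
DEFAULT_REFERENCE_WINDOW = (10, 20)


@dataclass(frozen=True)
class RawTrace:
    """One cell's raw strip-FRAP measurement.

    ``times`` are acquisition time stamps in seconds (strictly increasing,
    uniform spacing); ``strip_intensity`` and ``background_intensity`` are
    per-frame fluorescence in arbitrary units; ``bleach_frame_index`` is the
    index of the single bleach frame.
    """

    cell_id: str
    times: np.ndarray
    strip_intensity: np.ndarray
    background_intensity: np.ndarray
    bleach_frame_index: int
    condition_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        strip = np.asarray(self.strip_intensity, dtype=float)
        bg = np.asarray(self.background_intensity, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "strip_intensity", strip)
        object.__setattr__(self, "background_intensity", bg)
        if times.size == 0:
            raise InputError(f"trace {self.cell_id!r} is empty")
        if not (times.size == strip.size == bg.size):
            raise InputError(
                f"trace {self.cell_id!r}: times/strip/background lengths differ "
                f"({times.size}/{strip.size}/{bg.size})"
            )
        if np.any(np.diff(times) <= 0):
            raise InputError(f"trace {self.cell_id!r}: times must be strictly increasing")
        if not (0 <= self.bleach_frame_index < times.size):
            raise InputError(f"trace {self.cell_id!r}: bleach_frame_index out of range")
        if np.any(strip < 0) or np.any(bg < 0):
            raise InputError(f"trace {self.cell_id!r}: intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class NormalizedCurve:
    """Background-corrected RFI trace with pre-bleach reference mean forced to 100."""

    cell_id: str
    times: np.ndarray  # seconds, re-zeroed at the bleach frame
    rfi: np.ndarray
    prebleach_fi: float  # protein-level proxy, arbitrary units
    condition_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rfi", np.asarray(self.rfi, dtype=float))


@dataclass(frozen=True)
class MeanCurve:
    """Pointwise mean ± SD of normalized curves across the cells of one condition."""

    times: np.ndarray
    rfi_mean: np.ndarray
    rfi_sd: np.ndarray
    n_cells: int
    condition_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "rfi_mean", np.asarray(self.rfi_mean, dtype=float))
        object.__setattr__(self, "rfi_sd", np.asarray(self.rfi_sd, dtype=float))
        if self.n_cells < 1:
            raise InputError("MeanCurve requires n_cells >= 1")


def background_correct(trace: RawTrace) -> RawTrace:
    """Subtract the out-of-strip background from the in-strip signal per frame.

    Negative corrected values are clipped to 0 to keep intensities physical;
    the background channel of the returned trace is zeroed so the correction
    is idempotent.
    """
    corrected = np.clip(trace.strip_intensity - trace.background_intensity, 0.0, None)
    return replace(
        trace,
        strip_intensity=corrected,
        background_intensity=np.zeros_like(corrected),
    )


def normalize_prebleach(
    trace: RawTrace,
    reference_window: tuple[int, int] = DEFAULT_REFERENCE_WINDOW,
) -> NormalizedCurve:
    """Normalize a background-corrected trace so its pre-bleach reference mean is 100.

    ``reference_window`` is an inclusive (start, stop) pair of 0-based frame
    indices within the pre-bleach block; the default (10, 20) uses pre-bleach
    frames 10–20. The mean corrected intensity over that window becomes the
    pre-bleach FI (the protein-level proxy) and the whole trace is rescaled so
    this mean equals 100. Times are re-zeroed at the bleach frame.
    """
    lo, hi = reference_window
    if lo < 0 or hi < lo:
        raise InputError(f"invalid reference window {reference_window}")
    if hi >= trace.bleach_frame_index:
        raise InputError(
            f"reference window {reference_window} overlaps post-bleach frames "
            f"(bleach at frame {trace.bleach_frame_index})"
        )
    corrected = trace.strip_intensity  # contract: already background-corrected
    ref_mean = float(np.mean(corrected[lo : hi + 1]))
    if ref_mean <= 0:
        raise DegenerateTraceError(
            f"trace {trace.cell_id!r}: pre-bleach reference mean {ref_mean} is not positive"
        )
    rfi = 100.0 * corrected / ref_mean
    times = trace.times - trace.times[trace.bleach_frame_index]
    return NormalizedCurve(
        cell_id=trace.cell_id,
        times=times,
        rfi=rfi,
        prebleach_fi=ref_mean,
        condition_label=trace.condition_label,
    )


def preprocess_trace(
    trace: RawTrace,
    reference_window: tuple[int, int] = DEFAULT_REFERENCE_WINDOW,
) -> NormalizedCurve:
    """Background-correct then normalize a raw trace in one call."""
    return normalize_prebleach(background_correct(trace), reference_window)


def average_curves(curves: list[NormalizedCurve]) -> MeanCurve:
    """Pointwise mean and sample SD of normalized curves from one condition.

    Curves of unequal length are truncated to the shortest (acquisitions may
    stop a few frames apart); the truncation is logged. Time grids must agree
    on the overlap and all curves must share one condition label.
    """
    if not curves:
        raise InputError("average_curves requires at least one curve")
    labels = {c.condition_label for c in curves}
    if len(labels) > 1:
        raise InputError(f"curves mix condition labels: {sorted(labels)}")
    n = min(c.times.size for c in curves)
    if any(c.times.size != n for c in curves):
        logger.warning(
            "averaging curves of unequal length; truncating to %d frames", n
        )
    times = curves[0].times[:n]
    for c in curves[1:]:
        if not np.allclose(c.times[:n], times, rtol=0.0, atol=1e-9):
            raise InputError(f"curve {c.cell_id!r} is on a different time grid")
    stack = np.vstack([c.rfi[:n] for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n)
    return MeanCurve(
        times=times,
        rfi_mean=stack.mean(axis=0),
        rfi_sd=sd,
        n_cells=len(curves),
        condition_label=curves[0].condition_label,
    )


def prebleach_level_summary(
    curves: list[NormalizedCurve],
    reference_mean: float | None = None,
) -> tuple[float, float]:
    """Mean and sample SD of the pre-bleach FI across cells.

    Pre-bleach FI tracks total protein level. If ``reference_mean`` is given
    (typically the unperturbed condition's mean), both numbers are returned
    relative to it.
    """
    if not curves:
        raise InputError("prebleach_level_summary requires at least one curve")
    levels = np.array([c.prebleach_fi for c in curves], dtype=float)
    mean = float(levels.mean())
    sd = float(levels.std(ddof=1)) if levels.size > 1 else 0.0
    if reference_mean is not None:
        if reference_mean == 0:
            raise InputError("reference_mean must be non-zero")
        mean /= reference_mean
        sd /= reference_mean
    return mean, sd


# ---------------------------------------------------------------------------
# Tabular I/O


def read_traces_csv(
    path,
    bleach_frame: int | dict[str, int] | None = None,
) -> list[RawTrace]:
    """Read per-cell traces from a long-format delimited table.

    Expected columns: ``cell_id, condition, frame, time_s, strip_intensity,
    background_intensity`` and optionally ``bleach_frame``. The bleach frame
    may instead be supplied as a single integer or a per-cell mapping.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"cell_id", "condition", "frame", "time_s", "strip_intensity", "background_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        group = group.sort_values("frame")
        if "bleach_frame" in group.columns:
            bf = int(group["bleach_frame"].iloc[0])
        elif isinstance(bleach_frame, dict):
            try:
                bf = int(bleach_frame[str(cell_id)])
            except KeyError:
                raise InputError(f"no bleach frame declared for cell {cell_id!r}") from None
        elif bleach_frame is not None:
            bf = int(bleach_frame)
        else:
            raise InputError("bleach frame must be given per row, per cell, or globally")
        traces.append(
            RawTrace(
                cell_id=str(cell_id),
                times=group["time_s"].to_numpy(dtype=float),
                strip_intensity=group["strip_intensity"].to_numpy(dtype=float),
                background_intensity=group["background_intensity"].to_numpy(dtype=float),
                bleach_frame_index=bf,
                condition_label=str(group["condition"].iloc[0]),
            )
        )
    return traces


def curves_to_frame(curves: list[NormalizedCurve]) -> pd.DataFrame:
    """Long-format DataFrame of normalized curves (one row per cell × frame)."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "condition": c.condition_label,
                    "time_s": c.times,
                    "rfi": c.rfi,
                    "prebleach_fi": c.prebleach_fi,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def mean_curve_to_frame(curve: MeanCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": curve.condition_label,
            "time_s": curve.times,
            "rfi_mean": curve.rfi_mean,
            "rfi_sd": curve.rfi_sd,
            "n_cells": curve.n_cells,
        }
    )
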