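"""Vascular input-function extraction and resampling.

An input curve is the spatial mean of a concentration series over a vessel
mask.  Bolus onset is detected as the first frame whose value exceeds
``baseline mean + k * baseline SD`` (k = 3 by default, with a tiny absolute
floor so noise-free curves trigger on any true enhancement) sustained for
two consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DynamicSeries,
    EmptyMaskError,
    InputFunction,
    UnitsMismatchError,
)

__all__ = ["OnsetOptions", "detect_onset", "extract_input_function", "resample_input"]


@dataclass
class OnsetOptions:
    """Configuration for the baseline-plus-k*SD onset detector."""

    baseline_frames: int = 3
    k_sd: float = 3.0
    persistence_frames: int = 2
    abs_floor: float = 1e-9


def detect_onset(
    times_s: np.ndarray, conc: np.ndarray, opts: OnsetOptions | None = None
) -> float | None:
    """First sustained threshold crossing of a curve; None when none exists."""
    opts = opts or OnsetOptions()
    conc = np.asarray(conc, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    nb = min(opts.baseline_frames, conc.size)
    base = conc[:nb]
    thresh = base.mean() + max(opts.k_sd * base.std(), opts.abs_floor)
    above = conc > thresh
    need = opts.persistence_frames
    for i in range(conc.size):
        if above[i : i + need].size == need and above[i : i + need].all():
            return float(times_s[i])
    return None


def extract_input_function(
    series: DynamicSeries,
    vessel_mask: np.ndarray,
    source: str = "AIF_CT",
    onset_opts: OnsetOptions | None = None,
) -> InputFunction:
    """Mean concentration curve over a vessel mask with onset/peak metadata.

    When no frame ever exceeds the onset threshold the curve is returned
    with ``onset_s = None`` (the no-onset flag).
    """
    if not series.is_concentration():
        raise UnitsMismatchError("input-function extraction needs concentration units")
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != series.shape3d:
        raise ValueError("vessel mask shape does not match series grid")
    if not vessel_mask.any():
        raise EmptyMaskError("vessel mask is empty")
    curve = series.data[vessel_mask].mean(axis=0)
    onset = detect_onset(series.frame_times_s, curve, onset_opts)
    return InputFunction.from_curve(series.frame_times_s, curve, onset, source=source)


def resample_input(
    ifn: InputFunction,
    target_times_s: np.ndarray,
    allow_extrapolation: bool = False,
) -> InputFunction:
    """Piecewise-linear resampling of an input function onto a new grid.

    Times before the first knot are zero-extended (pre-onset); times beyond
    the last knot raise unless ``allow_extrapolation`` is set, in which case
    the last value is held.
    """
    target = np.asarray(target_times_s, dtype=float)
    if target.max() > ifn.times_s[-1] + 1e-9 and not allow_extrapolation:
        raise ValueError(
            "target grid extends beyond the sampled input function; "
            "pass allow_extrapolation=True to hold the last value"
        )
    conc = np.interp(target, ifn.times_s, ifn.conc, left=0.0,
                     right=float(ifn.conc[-1]))
    return InputFunction.from_curve(target, conc, ifn.onset_s, source=ifn.source)
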