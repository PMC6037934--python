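"""Variable-flip-angle (VFA) precontrast T1 mapping.

The spoiled FLASH steady-state signal ``S = M0 sin(a) (1-E1)/(1-E1 cos(a))``
is linear in the transformed coordinates y = S/sin(a), x = S/tan(a):
``y = E1 x + M0 (1 - E1)``, so a per-voxel linear regression across flip
angles (the classic DESPOT1 estimator) yields E1 from the slope and hence
T1 = -TR / ln(E1).  Voxels whose slope falls outside (0, 1) — a non-physical
E1, typically from noise or zero signal — are masked invalid.  An optional
nonlinear refinement re-fits the FLASH equation directly per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import ConfigError, EmptyMaskError

__all__ = ["T1Map", "fit_vfa_t1", "summarize_t10"]


@dataclass
class T1Map:
    """Voxel-wise precontrast T1 estimate with fit diagnostics."""

    t10_ms: np.ndarray
    m0: np.ndarray
    fit_r2: np.ndarray
    valid_mask: np.ndarray


def fit_vfa_t1(
    vfa_stack: np.ndarray,
    angles_deg,
    tr_ms: float,
    nonlinear_refine: bool = False,
) -> T1Map:
    """Fit (T1, M0) per voxel from a multi-flip-angle FLASH stack.

    ``vfa_stack`` is (x, y, z, n_angles) with volumes co-registered; at
    least two distinct angles are required.  Returns NaN T1/M0 outside the
    validity mask.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2 or np.unique(angles).size < 2:
        raise ConfigError("need at least two distinct flip angles")
    if tr_ms <= 0:
        raise ConfigError("tr_ms must be positive")
    stack = np.asarray(vfa_stack, dtype=float)
    if stack.ndim != 4 or stack.shape[3] != angles.size:
        raise ValueError("vfa_stack must be (x, y, z, n_angles)")

    rad = np.deg2rad(angles)
    with np.errstate(divide="ignore", invalid="ignore"):
        yv = stack / np.sin(rad)
        xv = stack / np.tan(rad)

    xm = xv.mean(axis=3, keepdims=True)
    ym = yv.mean(axis=3, keepdims=True)
    sxx = np.sum((xv - xm) ** 2, axis=3)
    sxy = np.sum((xv - xm) * (yv - ym), axis=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym[..., 0] - slope * xm[..., 0]
        ss_res = np.sum((yv - (slope[..., None] * xv + intercept[..., None])) ** 2, axis=3)
        ss_tot = np.sum((yv - ym) ** 2, axis=3)
        r2 = 1.0 - ss_res / ss_tot

    valid = (
        np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
        & np.isfinite(intercept) & (sxx > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -tr_ms / np.log(slope), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    r2 = np.where(valid & np.isfinite(r2), r2, np.nan)

    if nonlinear_refine:
        t1, m0 = _refine_nonlinear(stack, rad, tr_ms, t1, m0, valid)

    return T1Map(t10_ms=t1, m0=m0, fit_r2=r2, valid_mask=valid)


def _refine_nonlinear(stack, rad, tr_ms, t1, m0, valid):
    """Per-voxel Levenberg-Marquardt refinement of the FLASH fit."""
    sin_a, cos_a = np.sin(rad), np.cos(rad)
    t1 = t1.copy()
    m0 = m0.copy()
    for idx in np.argwhere(valid):
        i, j, k = idx
        s = stack[i, j, k, :]

        def resid(p):
            e1 = np.exp(-tr_ms / p[1])
            return p[0] * sin_a * (1 - e1) / (1 - e1 * cos_a) - s

        res = optimize.least_squares(
            resid, [m0[i, j, k], t1[i, j, k]],
            bounds=([0.0, 1.0], [np.inf, 2e4]),
        )
        m0[i, j, k], t1[i, j, k] = res.x
    return t1, m0


def summarize_t10(t1map: T1Map, mask: np.ndarray) -> dict:
    """Median, SD and count of valid T10 values inside a mask."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & t1map.valid_mask & np.isfinite(t1map.t10_ms)
    if not sel.any():
        raise EmptyMaskError("mask selects no valid T1 voxels")
    vals = t1map.t10_ms[sel]
    return {
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        "n": int(vals.size),
    }
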