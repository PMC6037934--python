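"""Signal-to-concentration conversion for DCE-CT and DCE-MRI series.

CT is linear: contrast concentration in mgI/mL is the baseline-subtracted
Hounsfield enhancement divided by a calibration slope (33 HU per mgI/mL by
default).

MRI uses the spoiled 3D-FLASH steady-state magnitude signal

    S = S0 * sin(a) * (1 - E1) / (1 - E1 cos(a)),   E1 = exp(-TR / T1)

with the T2*-decay factor exp(-TE/T2*) treated as a constant absorbed into
S0 (it cancels in the signal ratios the inversion uses), and the fast-
exchange linear relaxivity relation

    1/T1(t) = 1/T10 + r1 * C(t).

The inversion is closed form: S0 is inferred from the precontrast baseline
(mean of the first ``baseline_frames`` frames) and the known T10, each frame
is solved for E1 and hence T1(t), and concentration follows from the
relaxivity relation.  Frames whose signal ratio falls outside the invertible
range (E1 <= 0 or >= 1) are flagged, never silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    UNITS_HU,
    UNITS_MG_I_PER_ML,
    UNITS_MM,
    UNITS_SIGNAL,
    AcquisitionParams,
    DynamicSeries,
    UnitsMismatchError,
)

__all__ = [
    "flash_signal",
    "invert_flash",
    "ct_to_concentration",
    "mri_to_concentration",
    "MriConversionResult",
]


def flash_signal(
    c_mM: np.ndarray | float,
    t10_ms: np.ndarray | float,
    acq: AcquisitionParams,
    s0: np.ndarray | float = 1.0,
    flip_deg: float | None = None,
) -> np.ndarray | float:
    """Forward 3D-FLASH magnitude signal at concentration ``c_mM``.

    ``s0`` is the fully relaxed signal scale (proton density, coil gain and
    the constant T2* factor).  ``flip_deg`` overrides the dynamic flip angle
    in ``acq`` (used for VFA stacks).
    """
    c = np.asarray(c_mM, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10_ms must be positive")
    alpha = np.deg2rad(acq.flip_deg if flip_deg is None else flip_deg)
    r1_total = 1.0 / (t10 / 1000.0) + acq.r1_per_mM_s * c  # 1/s
    e1 = np.exp(-(acq.tr_ms / 1000.0) * r1_total)
    out = s0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
    return out if out.ndim else float(out)


def invert_flash(
    s: np.ndarray,
    s0: np.ndarray,
    t10_ms: np.ndarray,
    acq: AcquisitionParams,
    flip_deg: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the FLASH equation to concentration (mM).

    Returns ``(c_mM, valid)``.  Solving the signal equation for E1 gives
    ``E1 = (1 - A) / (1 - A cos a)`` with ``A = S / (S0 sin a)``; entries
    with E1 outside (0, 1) are marked invalid (NaN concentration).
    """
    alpha = np.deg2rad(acq.flip_deg if flip_deg is None else flip_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = s / (s0 * np.sin(alpha))
        e1 = (1.0 - a) / (1.0 - a * np.cos(alpha))
        valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
        t1_s = np.where(valid, -(acq.tr_ms / 1000.0) / np.log(e1), np.nan)
        c = (1.0 / t1_s - 1000.0 / np.asarray(t10_ms, float)) / acq.r1_per_mM_s
    c = np.where(valid, c, np.nan)
    return c, valid


def ct_to_concentration(
    series: DynamicSeries, acq: AcquisitionParams
) -> DynamicSeries:
    """Convert a Hounsfield-unit CT series to iodine concentration (mgI/mL).

    ``C(t) = (HU(t) - baseline) / hu_scaling`` with the baseline taken as
    the mean of the first ``acq.baseline_frames`` frames per voxel.
    """
    if series.modality != "CT" or series.units != UNITS_HU:
        raise UnitsMismatchError("ct_to_concentration requires a CT series in HU")
    if series.n_frames < acq.baseline_frames:
        raise ValueError("series shorter than baseline_frames")
    baseline = series.data[..., : acq.baseline_frames].mean(axis=3, keepdims=True)
    conc = (series.data - baseline) / acq.hu_scaling
    return DynamicSeries(
        data=conc,
        frame_times_s=series.frame_times_s,
        units=UNITS_MG_I_PER_ML,
        modality="CT",
        affine=series.affine,
    )


@dataclass
class MriConversionResult:
    """Concentration series plus per-voxel conversion diagnostics."""

    series: DynamicSeries
    valid_mask: np.ndarray          # voxels with usable T10 and baseline
    invertible: np.ndarray          # per voxel+frame flag for Eq. inversion
    n_masked_t10: int               # voxels dropped for missing/<=0 T10
    n_noninvertible: int            # voxel-frames outside the invertible range


def mri_to_concentration(
    series: DynamicSeries,
    t10: np.ndarray | float,
    acq: AcquisitionParams,
    s0: np.ndarray | None = None,
) -> MriConversionResult:
    """Convert a FLASH magnitude series to gadolinium concentration (mM).

    ``t10`` is either a 3D precontrast T1 map (ms) or a single fixed value
    applied everywhere.  By default the equilibrium signal S0 is inferred
    per voxel from the baseline mean (first ``acq.baseline_frames`` frames)
    and the supplied T10; alternatively a measured equilibrium-signal map
    (e.g. M0 from the VFA T1 fit) can be passed as ``s0``, in which case it
    is used directly and only the relaxivity relation depends on the
    assumed T10.  The two choices matter when the assumed T10 deviates from
    the true value: a baseline-inferred S0 rebases with the assumed T10,
    a measured S0 does not.  Every frame is inverted to T1(t) and then
    concentration.  Noise-induced negative concentrations are retained;
    non-invertible voxel-frames are flagged as NaN.
    """
    if series.modality != "MRI" or series.units != UNITS_SIGNAL:
        raise UnitsMismatchError(
            "mri_to_concentration requires an MRI series in signal units"
        )
    if series.n_frames < acq.baseline_frames:
        raise ValueError("series shorter than baseline_frames")

    shape3d = series.shape3d
    t10_map = np.broadcast_to(np.asarray(t10, dtype=float), shape3d)
    t10_ok = np.isfinite(t10_map) & (t10_map > 0)

    alpha = np.deg2rad(acq.flip_deg)
    if s0 is None:
        baseline = series.data[..., : acq.baseline_frames].mean(axis=3)
        with np.errstate(divide="ignore", invalid="ignore"):
            e10 = np.exp(-(acq.tr_ms / 1000.0) / (t10_map / 1000.0))
            s0 = baseline * (1.0 - e10 * np.cos(alpha)) / (
                np.sin(alpha) * (1.0 - e10)
            )
    else:
        s0 = np.broadcast_to(np.asarray(s0, dtype=float), shape3d)
    usable = t10_ok & np.isfinite(s0) & (s0 > 0)

    c, invertible = invert_flash(
        series.data,
        s0[..., None],
        t10_map[..., None],
        acq,
    )
    c = np.where(usable[..., None], c, np.nan)
    invertible = invertible & usable[..., None]

    n_masked = int(np.sum(~t10_ok))
    n_noninv = int(np.sum(usable[..., None] & ~invertible))
    out = DynamicSeries(
        data=c,
        frame_times_s=series.frame_times_s,
        units=UNITS_MM,
        modality="MRI",
        affine=series.affine,
    )
    return MriConversionResult(
        series=out,
        valid_mask=usable,
        invertible=invertible,
        n_masked_t10=n_masked,
        n_noninvertible=n_noninv,
    )
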