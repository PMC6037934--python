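"""Voxel-wise pharmacokinetic modelling for DCE series.

The core model is the modified Tofts model with an explicit vascular term
and a bolus-arrival delay ``z``::

    Ct(t) = Ktrans/(1 - Hct) * [Ca(t) (x) exp(-kep (t - z))] + Vb * Ca(t - z)

where ``Ca`` is the (whole-blood) input function, ``Ktrans`` the transfer
constant from plasma into the extravascular extracellular space (EES),
``kep`` the back-transfer rate, ``Vb`` the whole-blood volume fraction and
``Hct`` the hematocrit converting blood to plasma concentration.  The delay
``z`` is applied as a consistent time shift of the whole tissue response
(kernel and vascular term); shifting the kernel only is available via
``delay_vascular_term=False``.

Before fitting, voxels are classified by the temporal shape of their
enhancement (non-enhancing / vascular / tissue-enhancing) and only
tissue-enhancing voxels are passed to the nonlinear fit — a single-pass,
rule-based stand-in for iterative temporal dynamic analysis classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import (
    AcquisitionParams,
    DynamicSeries,
    EmptyMaskError,
    InputFunction,
    NoOnsetError,
    UnitsMismatchError,
)

__all__ = [
    "exp_convolve",
    "tofts_curve",
    "ToftsFit",
    "FitOptions",
    "ClassifierThresholds",
    "ParameterMaps",
    "classify_voxels",
    "fit_modified_tofts",
    "compute_iauc",
    "build_parameter_maps",
    "CLASS_NON_ENHANCING",
    "CLASS_VASCULAR",
    "CLASS_TISSUE",
]

log = logging.getLogger("dcequant")

CLASS_NON_ENHANCING = 0
CLASS_VASCULAR = 1
CLASS_TISSUE = 2


# --------------------------------------------------------------------------
# Convolution primitive
# --------------------------------------------------------------------------

def exp_convolve(c: np.ndarray, dt: float, k: float) -> np.ndarray:
    """Convolve a uniformly sampled curve with ``exp(-k t)``.

    Returns ``y(t_n) = integral_0^{t_n} c(s) exp(-k (t_n - s)) ds`` treating
    ``c`` as piecewise linear between samples, which makes the recursion
    exact for piecewise-linear inputs (no quadrature error beyond the
    linear-interpolation model of ``c``).

    Parameters
    ----------
    c : 1D array sampled at uniform spacing ``dt`` (seconds).
    dt : sample spacing in seconds.
    k : decay rate in 1/s (``k >= 0``).
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n == 0:
        return c.copy()
    y = np.empty(n)
    y[0] = 0.0
    if n == 1:
        return y
    a = c[:-1]
    b = (c[1:] - c[:-1]) / dt
    if k * dt < 1e-12:
        incr = 0.5 * dt * (c[:-1] + c[1:])
        y[1:] = np.cumsum(incr)
        return y
    e = np.exp(-k * dt)
    # integral over one interval of (a + b s) exp(-k (dt - s))
    incr = a * (1.0 - e) / k + b * (dt / k - (1.0 - e) / k**2)
    # y[n] = e * y[n-1] + incr[n-1]  -> first-order IIR filter
    y[1:] = signal.lfilter([1.0], [1.0, -e], incr)
    return y


def tofts_curve(
    times_out: np.ndarray,
    ca_fine: np.ndarray,
    t_fine: np.ndarray,
    ktrans_per_min: float,
    kep_per_min: float,
    vb: float,
    hct: float,
    z_s: float = 0.0,
    delay_vascular_term: bool = True,
) -> np.ndarray:
    """Evaluate the modified Tofts model at ``times_out``.

    ``ca_fine`` is the input function pre-sampled on the uniform fine grid
    ``t_fine`` (seconds, starting at 0).  Rates are given in min^-1 and
    converted internally; the returned curve is in the units of ``ca_fine``.
    """
    dt = float(t_fine[1] - t_fine[0])
    kep_s = kep_per_min / 60.0
    ktr_s = ktrans_per_min / 60.0
    conv = exp_convolve(ca_fine, dt, kep_s)
    ees = (ktr_s / (1.0 - hct)) * conv
    times_out = np.asarray(times_out, dtype=float)
    if delay_vascular_term:
        model = ees + vb * ca_fine
        return np.interp(times_out - z_s, t_fine, model, left=0.0)
    return (
        np.interp(times_out - z_s, t_fine, ees, left=0.0)
        + vb * np.interp(times_out, t_fine, ca_fine, left=0.0)
    )


# --------------------------------------------------------------------------
# Fit configuration and result types
# --------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Options for the bounded trust-region least-squares Tofts fit.

    Bounds keep pathological voxels finite: ktrans, kep in [0, 10] min^-1,
    vb in [0, 1], delay z in [0, 30] s.  ``ve_convention`` selects how the
    EES fraction is derived from the fitted constants: ``"model"`` uses
    ve = (Ktrans / (1 - Hct)) / kep (the amplitude of the printed model
    divided by kep), ``"classical"`` uses ve = Ktrans / kep.
    """

    fit_delay: bool = False
    delay_vascular_term: bool = True
    dt_fine_s: float = 0.1
    ktrans_bounds: tuple[float, float] = (0.0, 10.0)
    kep_bounds: tuple[float, float] = (0.0, 10.0)
    vb_bounds: tuple[float, float] = (0.0, 1.0)
    z_bounds_s: tuple[float, float] = (0.0, 30.0)
    ve_convention: str = "model"
    max_nfev: int = 200

    def __post_init__(self) -> None:
        if self.ve_convention not in ("model", "classical"):
            raise ValueError("ve_convention must be 'model' or 'classical'")


@dataclass
class ToftsFit:
    """Result of a single-voxel modified-Tofts fit (rates in min^-1)."""

    ktrans: float
    kep: float
    vb: float
    z_s: float
    ve: float
    sse: float
    converged: bool


def derive_ve(ktrans: float, kep: float, hct: float, convention: str) -> float:
    if kep <= 0:
        return float("nan")
    if convention == "model":
        return (ktrans / (1.0 - hct)) / kep
    return ktrans / kep


# --------------------------------------------------------------------------
# Voxel classification
# --------------------------------------------------------------------------

@dataclass
class ClassifierThresholds:
    """Thresholds for the single-pass temporal voxel classifier.

    A voxel is *non-enhancing* when its peak concentration stays below
    ``max(min_peak_frac * input peak, noise_k * baseline SD)``; *vascular*
    when its peak reaches ``vascular_peak_frac`` of the input peak and the
    time-to-peak is synchronous with the input within ``sync_tol_s``;
    otherwise *tissue-enhancing*.
    """

    min_peak_frac: float = 0.02
    noise_k: float = 4.0
    vascular_peak_frac: float = 0.5
    sync_tol_s: float = 10.0
    baseline_frames: int = 3


def classify_voxels(
    series: DynamicSeries,
    ifn: InputFunction,
    thresholds: ClassifierThresholds | None = None,
) -> np.ndarray:
    """Classify every voxel of a concentration series by temporal shape.

    Returns an int8 volume with codes ``CLASS_NON_ENHANCING`` (0),
    ``CLASS_VASCULAR`` (1) and ``CLASS_TISSUE`` (2).
    """
    if not series.is_concentration():
        raise UnitsMismatchError("classification requires a concentration series")
    th = thresholds or ClassifierThresholds()
    data = series.data
    nb = min(th.baseline_frames, data.shape[3])
    base_sd = data[..., :nb].std(axis=3)
    peak = data.max(axis=3)
    tpeak = series.frame_times_s[np.argmax(data, axis=3)]

    floor = np.maximum(th.min_peak_frac * ifn.peak_value, th.noise_k * base_sd)
    enhancing = peak > floor
    vascular = (
        enhancing
        & (peak >= th.vascular_peak_frac * ifn.peak_value)
        & (np.abs(tpeak - ifn.peak_time_s) <= th.sync_tol_s)
    )
    out = np.zeros(data.shape[:3], dtype=np.int8)
    out[enhancing] = CLASS_TISSUE
    out[vascular] = CLASS_VASCULAR
    return out


# --------------------------------------------------------------------------
# Modified Tofts fitting
# --------------------------------------------------------------------------

def _prepare_fine_grid(ifn: InputFunction, times: np.ndarray, dt: float):
    t_max = float(times[-1])
    n = int(np.floor(t_max / dt + 1e-9)) + 1
    t_fine = np.arange(n) * dt
    ca_fine = ifn.sample(t_fine)
    return t_fine, ca_fine


def fit_modified_tofts(
    ct_curve: np.ndarray,
    times: np.ndarray,
    ifn: InputFunction,
    hct: float,
    opts: FitOptions | None = None,
    _grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> ToftsFit:
    """Fit the modified Tofts model to one tissue concentration curve.

    Bounded trust-region least squares over (ktrans, kep, vb[, z]); a second
    start is tried when the first does not converge.  An all-zero curve
    short-circuits to a zero fit.  ``_grid`` allows callers fitting many
    voxels against the same input function to reuse the fine sampling grid.
    """
    opts = opts or FitOptions()
    curve = np.asarray(ct_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.size != times.size:
        raise ValueError("curve and times must have equal length")
    if hct >= 1.0:
        raise ValueError("hct must be < 1")

    if not np.any(curve != 0.0):
        return ToftsFit(0.0, 0.0, 0.0, 0.0, float("nan"), 0.0, True)

    if _grid is None:
        t_fine, ca_fine = _prepare_fine_grid(ifn, times, opts.dt_fine_s)
    else:
        t_fine, ca_fine = _grid

    fit_z = opts.fit_delay

    def model(p):
        z = p[3] if fit_z else 0.0
        return tofts_curve(
            times, ca_fine, t_fine, p[0], p[1], p[2], hct, z,
            delay_vascular_term=opts.delay_vascular_term,
        )

    def residuals(p):
        return model(p) - curve

    lo = [opts.ktrans_bounds[0], opts.kep_bounds[0], opts.vb_bounds[0]]
    hi = [opts.ktrans_bounds[1], opts.kep_bounds[1], opts.vb_bounds[1]]
    starts = [[0.1, 1.0, 0.02], [0.5, 3.0, 0.001]]
    x_scale = [0.1, 1.0, 0.01]
    if fit_z:
        lo.append(opts.z_bounds_s[0])
        hi.append(opts.z_bounds_s[1])
        starts[0].append(min(1.0, opts.z_bounds_s[1]))
        starts[1].append(min(5.0, opts.z_bounds_s[1]))
        x_scale.append(1.0)

    best = None
    for i, x0 in enumerate(starts):
        res = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            x_scale=x_scale, max_nfev=opts.max_nfev,
        )
        sse = float(2.0 * res.cost)
        if best is None or sse < best[1]:
            best = (res, sse)
        if i == 0 and res.success and sse <= 1e-3 * float(np.sum(curve**2)):
            break  # first start converged cleanly; skip the second
    res, sse = best
    p = res.x
    z = float(p[3]) if fit_z else 0.0
    return ToftsFit(
        ktrans=float(p[0]),
        kep=float(p[1]),
        vb=float(p[2]),
        z_s=z,
        ve=derive_ve(float(p[0]), float(p[1]), hct, opts.ve_convention),
        sse=sse,
        converged=bool(res.success),
    )


# --------------------------------------------------------------------------
# Semiquantitative parameters
# --------------------------------------------------------------------------

def compute_iauc(
    curve: np.ndarray,
    times: np.ndarray,
    onset_s: float | None,
    window_s: float = 90.0,
) -> float:
    """Initial area under the enhancement curve.

    Trapezoidal integral of the concentration curve from bolus onset to
    ``onset + window_s`` (the iAUC90 with the default 90 s window), with
    exact piecewise-linear interpolation of the window endpoints.  If the
    window extends past the last sample the integral is truncated at the
    sampled range and a warning is issued.
    """
    if onset_s is None:
        raise NoOnsetError("iAUC requires a defined bolus onset")
    times = np.asarray(times, dtype=float)
    curve = np.asarray(curve, dtype=float)
    t0 = float(onset_s)
    t1 = t0 + float(window_s)
    if t1 > times[-1]:
        warnings.warn(
            f"iAUC window end {t1:.1f}s beyond last frame {times[-1]:.1f}s; truncating",
            stacklevel=2,
        )
        t1 = float(times[-1])
    if t0 >= t1:
        return 0.0
    inner = times[(times > t0) & (times < t1)]
    knots = np.concatenate([[t0], inner, [t1]])
    vals = np.interp(knots, times, curve)
    return float(np.trapezoid(vals, knots))


# --------------------------------------------------------------------------
# Map building
# --------------------------------------------------------------------------

MAP_NAMES = ("ktrans", "kep", "ve", "vb", "z", "iauc", "sse")


@dataclass
class ParameterMaps:
    """Co-registered 3D parametric maps plus the voxel-class map.

    Voxels outside the fitted (tissue-enhancing) class carry NaN, never 0.
    """

    maps: dict[str, np.ndarray]
    voxel_class: np.ndarray
    frame_times_s: np.ndarray
    modality: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_nonconverged: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxel_class.shape

    def class_counts(self) -> dict[str, int]:
        vc = self.voxel_class
        return {
            "non_enhancing": int(np.sum(vc == CLASS_NON_ENHANCING)),
            "vascular": int(np.sum(vc == CLASS_VASCULAR)),
            "tissue": int(np.sum(vc == CLASS_TISSUE)),
        }


def build_parameter_maps(
    series: DynamicSeries,
    ifn: InputFunction,
    acq: AcquisitionParams,
    opts: FitOptions | None = None,
    thresholds: ClassifierThresholds | None = None,
    mask: np.ndarray | None = None,
    iauc_window_s: float = 90.0,
) -> ParameterMaps:
    """Classify and fit every voxel of a concentration series.

    Only tissue-enhancing voxels (optionally restricted by ``mask``) are
    fitted; their modified-Tofts parameters and iAUC are written into 3D
    maps.  The iAUC window is measured from the input-function onset.
    """
    if not series.is_concentration():
        raise UnitsMismatchError("build_parameter_maps requires concentration units")
    opts = opts or FitOptions()
    voxel_class = classify_voxels(series, ifn, thresholds)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != voxel_class.shape:
            raise ValueError("mask shape does not match series grid")
    else:
        mask = np.ones(voxel_class.shape, dtype=bool)

    shape = series.shape3d
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    times = series.frame_times_s
    grid = _prepare_fine_grid(ifn, times, opts.dt_fine_s)

    fit_idx = np.argwhere((voxel_class == CLASS_TISSUE) & mask)
    n_bad = 0
    for ix, iy, iz in fit_idx:
        curve = series.data[ix, iy, iz, :]
        if not np.all(np.isfinite(curve)):
            n_bad += 1  # non-invertible frames upstream; leave NaN
            continue
        fit = fit_modified_tofts(curve, times, ifn, acq.hct, opts, _grid=grid)
        if not fit.converged:
            n_bad += 1
        maps["ktrans"][ix, iy, iz] = fit.ktrans
        maps["kep"][ix, iy, iz] = fit.kep
        maps["ve"][ix, iy, iz] = fit.ve
        maps["vb"][ix, iy, iz] = fit.vb
        maps["z"][ix, iy, iz] = fit.z_s
        maps["sse"][ix, iy, iz] = fit.sse
        if ifn.onset_s is not None:
            maps["iauc"][ix, iy, iz] = compute_iauc(
                curve, times, ifn.onset_s, iauc_window_s
            )

    pm = ParameterMaps(
        maps=maps,
        voxel_class=voxel_class,
        frame_times_s=times,
        modality=series.modality,
        affine=series.affine,
        n_nonconverged=n_bad,
    )
    counts = pm.class_counts()
    n_fit = len(fit_idx)
    log.info(
        "parameter maps (%s): %d non-enhancing, %d vascular, %d tissue; "
        "fitted %d voxels, %d non-converged (%.1f%%)",
        series.modality, counts["non_enhancing"], counts["vascular"],
        counts["tissue"], n_fit, n_bad, 100.0 * n_bad / max(n_fit, 1),
    )
    return pm
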