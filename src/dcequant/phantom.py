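"""Digital reference phantom: paired DCE-CT / DCE-MRI series with known truth.

The phantom is a labelled volume (background, normal brain, tumour rim,
tumour core, artery, sagittal sinus) whose tissue labels carry known
modified-Tofts kinetics (Ktrans, kep, Vb, arrival delay z) and precontrast
T10.  A parametric population bolus — a gamma-variate first pass plus a
smaller delayed gamma-variate recirculation and a sigmoid-gated slow-washout
shoulder — drives every voxel:

* artery voxels carry the input function itself, sinus voxels a delayed and
  dispersed copy;
* tissue voxels follow the modified Tofts model;
* CT frames are rendered as ``HU = baseline + 33 * C`` (additive Gaussian
  noise), MRI frames through the 3D-FLASH signal equation (Rician noise),
  together with a variable-flip-angle precontrast stack.

Tumour labels can be given smooth within-label Ktrans heterogeneity so that
voxel-wise cross-modality correlation is a meaningful statistic rather than
a two-point comparison.  Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .conversion import flash_signal
from .core import (
    UNITS_HU,
    UNITS_MG_I_PER_ML,
    UNITS_MM,
    UNITS_SIGNAL,
    AcquisitionParams,
    DynamicSeries,
    InputFunction,
    SamplingSchedule,
    ScheduleError,
)
from .kinetics import exp_convolve, tofts_curve

__all__ = [
    "AIFShape",
    "generate_population_aif",
    "simulate_tissue_curve",
    "RegionKinetics",
    "PhantomSpec",
    "PhantomOutput",
    "reference_phantom",
    "render_ct_series",
    "render_mri_series",
    "aif_ct_preset",
    "aif_mri_preset",
]

LABEL_BACKGROUND = 0
LABEL_NORMAL = 1
LABEL_RIM = 2
LABEL_CORE = 3
LABEL_ARTERY = 4
LABEL_SINUS = 5


# --------------------------------------------------------------------------
# Population input function
# --------------------------------------------------------------------------

@dataclass
class AIFShape:
    """Parametric population bolus model.

    The first-pass term is a gamma variate normalised to unit peak,
    ``g(tau) = (tau/tp)^a * exp(a (1 - tau/tp))`` with its analytic mode at
    ``tau = tp_s`` after onset; ``amplitude`` is therefore (up to the small
    recirculation/washout contribution at the peak) the peak concentration.
    Recirculation is a second, delayed gamma variate; the washout shoulder
    is a sigmoid-gated slow exponential decay.
    """

    amplitude: float = 1.0
    onset_s: float = 10.0
    tp_s: float = 8.0
    alpha: float = 3.0
    recirc_frac: float = 0.25
    recirc_delay_s: float = 22.0
    recirc_tp_s: float = 14.0
    recirc_alpha: float = 2.0
    washout_frac: float = 0.2
    washout_mid_s: float = 30.0
    washout_width_s: float = 5.0
    washout_tau_s: float = 140.0

    @property
    def bolus_mode_s(self) -> float:
        """Analytic peak time of the first-pass gamma-variate term."""
        return self.onset_s + self.tp_s


def _gamma_variate(tau: np.ndarray, tp: float, alpha: float) -> np.ndarray:
    out = np.zeros_like(tau)
    pos = tau > 0
    r = tau[pos] / tp
    out[pos] = r**alpha * np.exp(alpha * (1.0 - r))
    return out


def generate_population_aif(
    shape: AIFShape, times_s: np.ndarray, source: str = "AIF_population"
) -> InputFunction:
    """Evaluate the parametric population input function at ``times_s``."""
    times_s = np.asarray(times_s, dtype=float)
    if times_s.ndim != 1 or (times_s.size > 1 and np.any(np.diff(times_s) <= 0)):
        raise ScheduleError("AIF times must be 1D and strictly increasing")
    if shape.amplitude < 0:
        raise ValueError("AIF amplitude must be non-negative")
    tau = times_s - shape.onset_s
    first = _gamma_variate(tau, shape.tp_s, shape.alpha)
    recirc = shape.recirc_frac * _gamma_variate(
        tau - shape.recirc_delay_s, shape.recirc_tp_s, shape.recirc_alpha
    )
    with np.errstate(over="ignore"):
        gate = 1.0 / (1.0 + np.exp(-(tau - shape.washout_mid_s) / shape.washout_width_s))
    washout = shape.washout_frac * gate * np.exp(
        -np.maximum(tau, 0.0) / shape.washout_tau_s
    )
    washout[tau <= 0] = 0.0
    conc = shape.amplitude * (first + recirc + washout)
    return InputFunction.from_curve(times_s, conc, onset_s=shape.onset_s, source=source)


def aif_ct_preset(dose: float = 60.0, onset_s: float = 7.0) -> AIFShape:
    """CT bolus preset: iodinated contrast, mgI/mL, early carotid arrival."""
    return AIFShape(amplitude=0.2 * dose, onset_s=onset_s)


def aif_mri_preset(dose: float = 15.0, onset_s: float = 27.0) -> AIFShape:
    """MRI bolus preset: gadolinium, mM; onset includes the 20 s injection delay."""
    return AIFShape(amplitude=0.2 * dose, onset_s=onset_s)


# --------------------------------------------------------------------------
# Single tissue curve
# --------------------------------------------------------------------------

def simulate_tissue_curve(
    ktrans: float,
    kep: float,
    vb: float,
    hct: float,
    z_s: float,
    aif: InputFunction,
    times_s: np.ndarray,
    dt_fine_s: float = 0.1,
    delay_vascular_term: bool = True,
) -> np.ndarray:
    """Modified-Tofts tissue curve at sample times (rates in min^-1).

    The convolution is evaluated on an internal uniform grid (``dt_fine_s``)
    and then sampled at ``times_s``.
    """
    if hct >= 1.0:
        raise ValueError("hct must be < 1")
    if ktrans < 0 or kep < 0 or not 0.0 <= vb <= 1.0:
        raise ValueError("kinetic parameters out of range")
    times_s = np.asarray(times_s, dtype=float)
    n = int(np.floor(float(times_s[-1]) / dt_fine_s + 1e-9)) + 1
    t_fine = np.arange(n) * dt_fine_s
    ca_fine = aif.sample(t_fine)
    return tofts_curve(
        times_s, ca_fine, t_fine, ktrans, kep, vb, hct, z_s,
        delay_vascular_term=delay_vascular_term,
    )


# --------------------------------------------------------------------------
# Phantom specification
# --------------------------------------------------------------------------

@dataclass
class RegionKinetics:
    """Per-label ground-truth kinetics and signal properties."""

    ktrans: float = 0.0        # min^-1
    kep: float = 0.0           # min^-1
    vb: float = 0.0            # fraction
    z_s: float = 0.0           # bolus arrival delay, s
    t10_ms: float = 1300.0
    s0: float = 1.0            # relative proton-density / gain scale
    baseline_hu: float = 35.0


@dataclass
class PhantomSpec:
    """Full description of a synthetic dual-modality phantom."""

    labels: np.ndarray
    kinetics: dict[int, RegionKinetics]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    heterogeneity: dict[int, float] = field(default_factory=dict)
    artery_label: int = LABEL_ARTERY
    sinus_label: int = LABEL_SINUS
    background_label: int = LABEL_BACKGROUND
    noise_model: str = "none"      # none | gaussian | rician
    noise_sigma: float = 0.0
    rng_seed: int = 0
    sinus_delay_s: float = 5.0
    sinus_dispersion_s: float = 3.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.kinetics) - {self.background_label}
        if missing:
            raise ValueError(f"labels without kinetics: {sorted(missing)}")
        for lab, k in self.kinetics.items():
            if k.ktrans < 0 or k.kep < 0:
                raise ValueError(f"label {lab}: rates must be non-negative")
            if not 0.0 <= k.vb <= 1.0:
                raise ValueError(f"label {lab}: vb must lie in [0, 1]")
            if k.t10_ms <= 0:
                raise ValueError(f"label {lab}: t10_ms must be positive")
            if lab not in (self.artery_label, self.sinus_label) and k.kep > 0:
                h = 1.0 + self.heterogeneity.get(lab, 0.0)
                ve = (h * k.ktrans / 0.6) / k.kep  # model convention at Hct 0.4
                if ve > 1.0:
                    raise ValueError(
                        f"label {lab}: implied ve {ve:.2f} exceeds 1"
                    )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)

    def tissue_labels(self) -> list[int]:
        return [
            lab for lab in self.kinetics
            if lab not in (self.artery_label, self.sinus_label)
        ]


def _smooth_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean random field with unit maximum amplitude."""
    coarse = rng.standard_normal([max(2, s // 5) for s in shape])
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    f = ndimage.zoom(coarse, zoom, order=1)[: shape[0], : shape[1], : shape[2]]
    f -= f.mean()
    amax = np.abs(f).max()
    return f / amax if amax > 0 else f


def _truth_maps(
    spec: PhantomSpec, hct: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    shape = spec.grid_shape
    maps = {k: np.full(shape, np.nan) for k in ("ktrans", "kep", "ve", "vb", "z", "t10")}
    het_field = _smooth_field(shape, rng) if spec.heterogeneity else None
    for lab, k in spec.kinetics.items():
        m = spec.labels == lab
        maps["t10"][m] = k.t10_ms
        if lab in (spec.artery_label, spec.sinus_label):
            maps["vb"][m] = 1.0
            continue
        ktr = np.full(int(m.sum()), k.ktrans)
        h = spec.heterogeneity.get(lab, 0.0)
        if h > 0 and het_field is not None:
            ktr = k.ktrans * np.clip(1.0 + h * het_field[m], 1.0 - h, 1.0 + h)
        maps["ktrans"][m] = ktr
        maps["kep"][m] = k.kep
        maps["vb"][m] = k.vb
        maps["z"][m] = k.z_s
        maps["ve"][m] = (ktr / (1.0 - hct)) / k.kep if k.kep > 0 else np.nan
    return maps


def _concentration_movie(
    spec: PhantomSpec,
    schedule: SamplingSchedule,
    aif_shape: AIFShape,
    hct: float,
    truth: dict[str, np.ndarray],
    dt_fine_s: float = 0.1,
) -> tuple[np.ndarray, InputFunction]:
    """Noise-free concentration 4D array and the fine-grid input function."""
    times = schedule.frame_times_s
    n_fine = int(np.floor(float(times[-1]) / dt_fine_s + 1e-9)) + 1
    t_fine = np.arange(n_fine) * dt_fine_s
    aif = generate_population_aif(aif_shape, t_fine)
    ca_fine = aif.conc

    conc = np.zeros(spec.grid_shape + (times.size,))

    # vessels
    art = spec.labels == spec.artery_label
    if art.any():
        conc[art] = np.interp(times, t_fine, ca_fine, left=0.0)
    sin = spec.labels == spec.sinus_label
    if sin.any():
        disp = exp_convolve(ca_fine, dt_fine_s, 1.0 / spec.sinus_dispersion_s)
        disp /= spec.sinus_dispersion_s
        conc[sin] = np.interp(times - spec.sinus_delay_s, t_fine, disp, left=0.0)

    # tissue labels: convolution depends only on the label's kep, so the
    # per-voxel curve is a linear combination of two label-level base curves
    for lab in spec.tissue_labels():
        m = spec.labels == lab
        if not m.any():
            continue
        k = spec.kinetics[lab]
        conv = exp_convolve(ca_fine, dt_fine_s, k.kep / 60.0)
        t_shift = times - k.z_s
        ees_base = np.interp(t_shift, t_fine, conv, left=0.0) / (1.0 - hct) / 60.0
        ca_z = np.interp(t_shift, t_fine, ca_fine, left=0.0)
        ktr_vox = truth["ktrans"][m]
        conc[m] = ktr_vox[:, None] * ees_base[None, :] + k.vb * ca_z[None, :]
    return conc, aif


def _require_precontrast(schedule: SamplingSchedule, onset_s: float) -> None:
    if not np.any(schedule.frame_times_s < onset_s):
        raise ScheduleError("schedule has no precontrast frame before bolus onset")


@dataclass
class PhantomOutput:
    """Rendered phantom: measured series plus every piece of ground truth."""

    series: DynamicSeries
    conc_truth: DynamicSeries
    truth: dict[str, np.ndarray]
    labels: np.ndarray
    aif: InputFunction
    t10_map: np.ndarray
    spec: PhantomSpec
    vfa_stack: np.ndarray | None = None     # (x, y, z, n_angles)
    vfa_angles_deg: tuple[float, ...] | None = None


# --------------------------------------------------------------------------
# Renderers
# --------------------------------------------------------------------------

def render_ct_series(
    spec: PhantomSpec,
    schedule: SamplingSchedule,
    acq: AcquisitionParams,
    aif_shape: AIFShape | None = None,
) -> PhantomOutput:
    """Render the phantom as a DCE-CT series in Hounsfield units.

    ``HU(t) = baseline_HU + hu_scaling * C(t) (+ Gaussian noise)``; the
    precontrast frames carry baseline only.
    """
    if aif_shape is None:
        aif_shape = aif_ct_preset(acq.dose)
    _require_precontrast(schedule, aif_shape.onset_s)
    rng = np.random.default_rng(spec.rng_seed)
    truth = _truth_maps(spec, acq.hct, rng)
    conc, aif = _concentration_movie(spec, schedule, aif_shape, acq.hct, truth)

    base_hu = np.full(spec.grid_shape, -1000.0)
    for lab, k in spec.kinetics.items():
        base_hu[spec.labels == lab] = k.baseline_hu

    hu = base_hu[..., None] + acq.hu_scaling * conc
    if spec.noise_model == "gaussian" and spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)
    elif spec.noise_model == "rician" and spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, size=hu.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, size=hu.shape)
        hu = np.sqrt((hu + n1) ** 2 + n2**2)

    aif.source = "AIF_CT"
    return PhantomOutput(
        series=DynamicSeries(hu, schedule.frame_times_s, UNITS_HU, "CT"),
        conc_truth=DynamicSeries(
            conc, schedule.frame_times_s, UNITS_MG_I_PER_ML, "CT"
        ),
        truth=truth,
        labels=spec.labels,
        aif=aif,
        t10_map=truth["t10"],
        spec=spec,
    )


def render_mri_series(
    spec: PhantomSpec,
    schedule: SamplingSchedule,
    acq: AcquisitionParams,
    aif_shape: AIFShape | None = None,
    s0_scale: float = 1000.0,
    vfa_noise: bool = True,
) -> PhantomOutput:
    """Render the phantom as a 3D-FLASH DCE-MRI series plus a VFA stack.

    Per voxel the label T10 and the simulated concentration set T1(t)
    through the relaxivity relation and the FLASH equation gives the
    magnitude signal; Rician noise is applied to magnitudes.  The VFA stack
    is rendered at ``acq.vfa_angles_deg`` with C = 0.
    """
    if aif_shape is None:
        aif_shape = aif_mri_preset(acq.dose)
    _require_precontrast(schedule, aif_shape.onset_s)
    rng = np.random.default_rng(spec.rng_seed)
    truth = _truth_maps(spec, acq.hct, rng)
    conc, aif = _concentration_movie(spec, schedule, aif_shape, acq.hct, truth)

    t10 = np.full(spec.grid_shape, np.nan)
    s0 = np.zeros(spec.grid_shape)
    for lab, k in spec.kinetics.items():
        m = spec.labels == lab
        t10[m] = k.t10_ms
        s0[m] = k.s0 * s0_scale
    t10_safe = np.where(np.isfinite(t10) & (t10 > 0), t10, 1000.0)

    sig = flash_signal(conc, t10_safe[..., None], acq, s0[..., None])

    angles = tuple(acq.vfa_angles_deg)
    vfa = np.stack(
        [flash_signal(0.0, t10_safe, acq, s0, flip_deg=a) for a in angles],
        axis=-1,
    )

    if spec.noise_model in ("gaussian", "rician") and spec.noise_sigma > 0:
        def _rician(x):
            n1 = rng.normal(0.0, spec.noise_sigma, size=x.shape)
            if spec.noise_model == "gaussian":
                return x + n1
            n2 = rng.normal(0.0, spec.noise_sigma, size=x.shape)
            return np.sqrt((x + n1) ** 2 + n2**2)

        sig = _rician(sig)
        if vfa_noise:
            vfa = _rician(vfa)

    aif.source = "AIF_population"
    return PhantomOutput(
        series=DynamicSeries(sig, schedule.frame_times_s, UNITS_SIGNAL, "MRI"),
        conc_truth=DynamicSeries(conc, schedule.frame_times_s, UNITS_MM, "MRI"),
        truth=truth,
        labels=spec.labels,
        aif=aif,
        t10_map=t10,
        spec=spec,
        vfa_stack=vfa,
        vfa_angles_deg=angles,
    )


# --------------------------------------------------------------------------
# Reference phantom geometry
# --------------------------------------------------------------------------

def reference_phantom(
    grid_shape: tuple[int, int, int] = (24, 24, 8),
    rng_seed: int = 0,
    noise_model: str = "none",
    noise_sigma: float = 0.0,
    heterogeneity: float = 0.3,
) -> PhantomSpec:
    """Default phantom: head ellipsoid, two-compartment tumour, two vessels.

    Tumour rim (fast leaky kinetics) and core (slower, less perfused) sit in
    normal brain with an intact-barrier trickle; an artery column carries
    the input function and a sinus column a delayed dispersed copy.
    ``heterogeneity`` adds smooth within-tumour Ktrans variation (+/- the
    given fraction).
    """
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    head = (
        ((x - cx) / (0.46 * nx)) ** 2
        + ((y - cy) / (0.46 * ny)) ** 2
        + ((z - cz) / (0.48 * nz)) ** 2
    ) <= 1.0

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[head] = LABEL_NORMAL

    tx, ty = cx + 0.18 * nx, cy
    r_t = 0.22 * nx
    d_tumor = np.sqrt((x - tx) ** 2 + (y - ty) ** 2 + ((z - cz) * nx / nz / 2.2) ** 2)
    tumor = (d_tumor <= r_t) & head
    labels[tumor] = LABEL_RIM
    labels[(d_tumor <= 0.55 * r_t) & head] = LABEL_CORE

    def _column(px, py, radius=1.2):
        return ((x - px) ** 2 + (y - py) ** 2 <= radius**2) & head

    labels[_column(0.28 * nx, 0.28 * ny)] = LABEL_ARTERY
    labels[_column(0.28 * nx, 0.72 * ny)] = LABEL_SINUS

    kinetics = {
        LABEL_NORMAL: RegionKinetics(
            ktrans=0.01, kep=0.4, vb=0.02, z_s=0.0,
            t10_ms=1300.0, s0=1.0, baseline_hu=35.0,
        ),
        LABEL_RIM: RegionKinetics(
            ktrans=0.25, kep=0.9, vb=0.05, z_s=2.0,
            t10_ms=1500.0, s0=1.05, baseline_hu=40.0,
        ),
        LABEL_CORE: RegionKinetics(
            ktrans=0.08, kep=0.5, vb=0.02, z_s=3.0,
            t10_ms=1800.0, s0=0.95, baseline_hu=38.0,
        ),
        LABEL_ARTERY: RegionKinetics(t10_ms=1650.0, s0=1.1, baseline_hu=45.0),
        LABEL_SINUS: RegionKinetics(t10_ms=1650.0, s0=1.1, baseline_hu=45.0),
    }
    het = {LABEL_RIM: heterogeneity, LABEL_CORE: heterogeneity} if heterogeneity else {}
    return PhantomSpec(
        labels=labels,
        kinetics=kinetics,
        heterogeneity=het,
        noise_model=noise_model,
        noise_sigma=noise_sigma,
        rng_seed=rng_seed,
    )


def tumor_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the tumour labels (rim + core)."""
    return np.isin(spec.labels, (LABEL_RIM, LABEL_CORE))
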