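"""Shared containers for dynamic contrast-enhanced (DCE) perfusion analysis.

Units are explicit throughout the package: frame times in seconds, rate
constants (Ktrans, kep) in min^-1, volume fractions dimensionless, T1/T10 in
milliseconds, CT concentration in mgI/mL, MRI concentration in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AcquisitionParams",
    "SamplingSchedule",
    "DynamicSeries",
    "InputFunction",
    "ConfigError",
    "ScheduleError",
    "UnitsMismatchError",
    "EmptyMaskError",
    "NoOnsetError",
]

# Recognised unit tags for DynamicSeries.
UNITS_HU = "HU"
UNITS_SIGNAL = "signal_au"
UNITS_MG_I_PER_ML = "mgI_per_mL"
UNITS_MM = "mM"
CONCENTRATION_UNITS = (UNITS_MG_I_PER_ML, UNITS_MM)


class ConfigError(ValueError):
    """Invalid acquisition or analysis configuration."""


class ScheduleError(ValueError):
    """Invalid sampling schedule (non-monotone times, missing precontrast frame...)."""


class UnitsMismatchError(ValueError):
    """Operation applied to a series in the wrong units or modality."""


class EmptyMaskError(ValueError):
    """A mask selects no usable voxels."""


class NoOnsetError(ValueError):
    """Bolus onset is undefined for a curve (nothing ever enhances)."""


@dataclass
class AcquisitionParams:
    """Acquisition constants needed for signal-to-concentration conversion.

    Defaults follow a 3 T 3D-FLASH brain protocol (TR/TE = 4.8/1.86 ms,
    dynamic flip angle 20 deg, VFA angles 2/10/20/30 deg, gadolinium
    relaxivity 3.3 L/mmol/s) and a DCE-CT calibration of 33 HU per mgI/mL.
    ``dose`` is the injected contrast amount used only for iAUC
    normalisation (mL iodinated contrast for CT, mmol Gd for MRI).
    """

    tr_ms: float = 4.8
    te_ms: float = 1.86
    flip_deg: float = 20.0
    vfa_angles_deg: tuple[float, ...] = (2.0, 10.0, 20.0, 30.0)
    r1_per_mM_s: float = 3.3
    hct: float = 0.4
    hu_scaling: float = 33.0
    dose: float = 1.0
    baseline_frames: int = 3

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ConfigError("tr_ms must be positive")
        if not 0.0 < self.flip_deg < 180.0:
            raise ConfigError("flip_deg must lie in (0, 180)")
        if self.r1_per_mM_s <= 0:
            raise ConfigError("r1 must be positive")
        if not 0.0 <= self.hct < 1.0:
            raise ConfigError("hct must lie in [0, 1)")
        if self.hu_scaling <= 0:
            raise ConfigError("hu_scaling must be positive")
        if self.baseline_frames < 1:
            raise ConfigError("baseline_frames must be >= 1")

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)


@dataclass
class SamplingSchedule:
    """Frame acquisition times in seconds from the start of scanning."""

    frame_times_s: np.ndarray
    preset: str = "custom"

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times_s, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ScheduleError("schedule needs at least two frame times")
        if np.any(np.diff(t) <= 0):
            raise ScheduleError("frame times must be strictly increasing")
        self.frame_times_s = t

    @property
    def n_frames(self) -> int:
        return int(self.frame_times_s.size)

    @classmethod
    def ct_brain(cls) -> "SamplingSchedule":
        """Nonuniform brain DCE-CT schedule.

        One precontrast frame at t=0, then every 1.5 s for the first 30 s,
        every 5 s up to 120 s and every 10 s up to 180 s (45 frames total).
        """
        t = np.concatenate(
            [
                [0.0],
                np.arange(1.5, 30.0 + 1e-9, 1.5),
                np.arange(35.0, 120.0 + 1e-9, 5.0),
                np.arange(130.0, 180.0 + 1e-9, 10.0),
            ]
        )
        return cls(t, preset="ct_brain")

    @classmethod
    def mri_flash(cls, n_frames: int = 45, dt_s: float = 5.8) -> "SamplingSchedule":
        """Uniform 3D-FLASH dynamic schedule: 45 repetitions at 5.8 s."""
        return cls(np.arange(n_frames) * dt_s, preset="mri_flash")


@dataclass
class DynamicSeries:
    """A 4D dynamic image series: spatial volume per time frame.

    ``data`` is (x, y, z, t); ``frame_times_s`` matches the temporal axis.
    """

    data: np.ndarray
    frame_times_s: np.ndarray
    units: str
    modality: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries.data must be 4D (x, y, z, t)")
        if self.frame_times_s.size != self.data.shape[3]:
            raise ScheduleError(
                f"{self.frame_times_s.size} frame times for "
                f"{self.data.shape[3]} frames"
            )
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ScheduleError("frame times must be strictly increasing")
        if self.modality not in ("CT", "MRI"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times_s.size)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def is_concentration(self) -> bool:
        return self.units in CONCENTRATION_UNITS


@dataclass
class InputFunction:
    """A plasma/blood input curve: concentration versus time.

    ``onset_s`` is the bolus arrival time (None when no onset was detected);
    peak metadata is always derived from the curve itself.
    """

    times_s: np.ndarray
    conc: np.ndarray
    onset_s: float | None
    peak_value: float
    peak_time_s: float
    source: str = "AIF_population"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.size != self.conc.size:
            raise ValueError("times and concentrations must be 1D and equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ScheduleError("input-function times must be strictly increasing")

    @classmethod
    def from_curve(
        cls,
        times_s: np.ndarray,
        conc: np.ndarray,
        onset_s: float | None,
        source: str = "AIF_population",
    ) -> "InputFunction":
        conc = np.asarray(conc, dtype=float)
        times_s = np.asarray(times_s, dtype=float)
        i = int(np.argmax(conc)) if conc.size else 0
        return cls(
            times_s=times_s,
            conc=conc,
            onset_s=onset_s,
            peak_value=float(conc[i]) if conc.size else 0.0,
            peak_time_s=float(times_s[i]) if conc.size else 0.0,
            source=source,
        )

    def sample(self, times_s: np.ndarray) -> np.ndarray:
        """Piecewise-linear evaluation, zero-extended before the first knot."""
        return np.interp(np.asarray(times_s, float), self.times_s, self.conc,
                         left=0.0, right=float(self.conc[-1]))
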