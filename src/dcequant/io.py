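"""NIfTI / sidecar / CSV / YAML I/O and the study configuration schema.

Dynamic series are stored as 4D NIfTI-1 (.nii or .nii.gz) plus a JSON
sidecar carrying per-frame acquisition times, units and modality — timing
never lives in the image file.  All volumes keep their affine; nothing is
silently reoriented or resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AcquisitionParams, ConfigError, DynamicSeries, InputFunction
from .kinetics import ParameterMaps

__all__ = [
    "save_dynamic_series",
    "load_dynamic_series",
    "save_volume",
    "load_volume",
    "save_input_function",
    "load_input_function",
    "save_parameter_maps",
    "ModalityConfig",
    "StudyConfig",
    "load_study_config",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def save_dynamic_series(
    series: DynamicSeries, path: str | Path, extra: dict | None = None
) -> Path:
    """Write a 4D series as NIfTI plus its JSON timing sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(series.data, series.affine), str(path))
    sidecar = {
        "frame_times_s": series.frame_times_s.tolist(),
        "units": series.units,
        "modality": series.modality,
    }
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_dynamic_series(
    path: str | Path, sidecar: str | Path | None = None
) -> DynamicSeries:
    """Load a 4D NIfTI series; timing and units come from the sidecar."""
    path = Path(path)
    sc_path = Path(sidecar) if sidecar else _sidecar_path(path)
    if not sc_path.exists():
        raise ConfigError(f"missing timing sidecar {sc_path}")
    meta = json.loads(sc_path.read_text())
    for key in ("frame_times_s", "units", "modality"):
        if key not in meta:
            raise ConfigError(f"sidecar {sc_path} lacks {key!r}")
    img = nib.load(str(path))
    return DynamicSeries(
        data=np.asarray(img.dataobj, dtype=float),
        frame_times_s=np.asarray(meta["frame_times_s"], dtype=float),
        units=meta["units"],
        modality=meta["modality"],
        affine=img.affine,
    )


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(np.asarray(data, dtype=float),
                        np.eye(4) if affine is None else affine),
        str(path),
    )
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_input_function(ifn: InputFunction, csv_path: str | Path) -> Path:
    """Serialise as CSV (time_s, conc) plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": ifn.times_s, "conc": ifn.conc}).to_csv(
        csv_path, index=False
    )
    meta = {
        "onset_s": ifn.onset_s,
        "peak_value": ifn.peak_value,
        "peak_time_s": ifn.peak_time_s,
        "source": ifn.source,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return csv_path


def load_input_function(csv_path: str | Path) -> InputFunction:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return InputFunction.from_curve(
        df["time_s"].to_numpy(),
        df["conc"].to_numpy(),
        meta.get("onset_s"),
        source=meta.get("source", "AIF_CT"),
    )


def save_parameter_maps(pm: ParameterMaps, out_dir: str | Path) -> Path:
    """Write one NIfTI per parameter, the class map and a per-voxel CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, vol in pm.maps.items():
        save_volume(vol, out / f"{name}.nii.gz", pm.affine)
    nib.save(
        nib.Nifti1Image(pm.voxel_class.astype(np.int16), pm.affine),
        str(out / "voxel_class.nii.gz"),
    )
    fitted = np.isfinite(pm.maps["ktrans"])
    idx = np.argwhere(fitted)
    table = pd.DataFrame({"i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2]})
    table["class"] = pm.voxel_class[fitted]
    for name in pm.maps:
        table[name] = pm.maps[name][fitted]
    table.to_csv(out / "voxels.csv", index=False, float_format="%.8g")
    return out


# --------------------------------------------------------------------------
# Study configuration
# --------------------------------------------------------------------------

@dataclass
class ModalityConfig:
    """Per-modality inputs and analysis choices for a pipeline run."""

    series: str
    sidecar: str | None = None
    tumor_mask: str | None = None
    vessel_mask: str | None = None
    vfa_stack: str | None = None
    vfa_angles_deg: list | None = None
    t10_mode: str = "fixed"          # fixed | map (MRI only)
    t10_fixed_ms: float = 1600.0
    t10_map: str | None = None
    s0_source: str = "baseline"      # baseline | vfa (use fitted M0 as S0)
    aif_mode: str = "extract"        # extract | population
    population_aif: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)

    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(**self.acquisition)


@dataclass
class StudyConfig:
    """Whole-study configuration for :func:`dcequant.pipeline.run_pipeline`."""

    modalities: dict[str, ModalityConfig]
    out_dir: str
    seed: int = 0
    iauc_window_s: float = 90.0
    common_grid: tuple[int, int, int] | None = None
    fit: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    compare: bool = True


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Relative paths are resolved against the config file's directory; every
    referenced file must exist; ``t10_mode`` must be exactly ``fixed`` or
    ``map`` (with a T10 source present for ``map``).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent
    modalities = {}
    for name, m in raw.get("modalities", {}).items():
        mc = ModalityConfig(**m)
        for attr in ("series", "sidecar", "tumor_mask", "vessel_mask",
                     "vfa_stack", "t10_map"):
            p = getattr(mc, attr)
            if p is not None:
                p = str((base / p).resolve()) if not Path(p).is_absolute() else p
                setattr(mc, attr, p)
                if not Path(p).exists():
                    raise ConfigError(f"{name}.{attr}: no such file {p}")
        if mc.t10_mode not in ("fixed", "map"):
            raise ConfigError("t10_mode must be 'fixed' or 'map'")
        if mc.t10_mode == "map" and mc.t10_map is None and mc.vfa_stack is None:
            raise ConfigError("t10_mode 'map' needs t10_map or vfa_stack")
        if mc.aif_mode not in ("extract", "population"):
            raise ConfigError("aif_mode must be 'extract' or 'population'")
        if mc.s0_source not in ("baseline", "vfa"):
            raise ConfigError("s0_source must be 'baseline' or 'vfa'")
        if mc.s0_source == "vfa" and mc.vfa_stack is None:
            raise ConfigError("s0_source 'vfa' needs a vfa_stack")
        modalities[name] = mc
    if not modalities:
        raise ConfigError("config defines no modalities")
    out_dir = raw.get("out_dir", "dcequant_out")
    if not Path(out_dir).is_absolute():
        out_dir = str((base / out_dir).resolve())
    grid = raw.get("common_grid")
    return StudyConfig(
        modalities=modalities,
        out_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        iauc_window_s=float(raw.get("iauc_window_s", 90.0)),
        common_grid=tuple(grid) if grid else None,
        fit=raw.get("fit", {}),
        classifier=raw.get("classifier", {}),
        compare=bool(raw.get("compare", True)),
    )
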