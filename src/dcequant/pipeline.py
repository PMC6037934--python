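"""Pipeline driver: convert -> (T1 map) -> input function -> fit -> compare.

:func:`run_pipeline` executes the full per-modality analysis described by a
:class:`~dcequant.io.StudyConfig` and, when two modalities are present,
compares their parameter maps voxel-wise on a common grid.  Each stage
failure is re-raised tagged with its stage name; outputs written before the
failure are retained.

:func:`write_phantom_study` renders the reference phantom to disk in the
exact file layout the pipeline consumes, so a complete synthetic study can
be generated, analysed and compared end to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aif import extract_input_function
from .conversion import ct_to_concentration, mri_to_concentration
from .core import AcquisitionParams, DynamicSeries, InputFunction
from .io import (
    ModalityConfig,
    StudyConfig,
    load_dynamic_series,
    load_volume,
    save_dynamic_series,
    save_input_function,
    save_parameter_maps,
    save_volume,
)
from .kinetics import (
    ClassifierThresholds,
    FitOptions,
    ParameterMaps,
    build_parameter_maps,
)
from .phantom import (
    AIFShape,
    PhantomSpec,
    SamplingSchedule,
    aif_ct_preset,
    aif_mri_preset,
    generate_population_aif,
    reference_phantom,
    render_ct_series,
    render_mri_series,
    tumor_mask,
)
from .stats import histogram_moments, normalize_iauc, voxelwise_compare
from .t1fit import fit_vfa_t1

__all__ = ["PipelineError", "run_pipeline", "write_phantom_study"]

log = logging.getLogger("dcequant")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("convert")
def _convert(series: DynamicSeries, mc: ModalityConfig, acq: AcquisitionParams,
             out: Path):
    if series.modality == "CT":
        return ct_to_concentration(series, acq), {}
    t1map = None
    if mc.vfa_stack is not None and (mc.t10_mode == "map" or mc.s0_source == "vfa"):
        t1map = fit_vfa_t1(load_volume(mc.vfa_stack), mc.vfa_angles_deg, acq.tr_ms)
    if mc.t10_mode == "map":
        if mc.t10_map is not None:
            t10 = load_volume(mc.t10_map)
        else:
            t10 = t1map.t10_ms
            save_volume(t10, out / "t10_fitted.nii.gz", series.affine)
    else:
        t10 = float(mc.t10_fixed_ms)
    s0 = t1map.m0 if (mc.s0_source == "vfa" and t1map is not None) else None
    res = mri_to_concentration(series, t10, acq, s0=s0)
    diag = {
        "n_masked_t10": res.n_masked_t10,
        "n_noninvertible": res.n_noninvertible,
    }
    return res.series, diag


@_stage("aif")
def _input_function(conc: DynamicSeries, mc: ModalityConfig) -> InputFunction:
    if mc.aif_mode == "extract":
        if mc.vessel_mask is None:
            raise ValueError("aif_mode 'extract' needs a vessel_mask")
        mask = load_volume(mc.vessel_mask) > 0.5
        return extract_input_function(conc, mask, source=f"AIF_{conc.modality}")
    t_max = float(conc.frame_times_s[-1])
    t_fine = np.arange(0.0, t_max + 0.1, 0.1)
    return generate_population_aif(AIFShape(**mc.population_aif), t_fine)


@_stage("fitdce")
def _fit(conc: DynamicSeries, ifn: InputFunction, acq: AcquisitionParams,
         cfg: StudyConfig) -> ParameterMaps:
    return build_parameter_maps(
        conc, ifn, acq,
        opts=FitOptions(**cfg.fit),
        thresholds=ClassifierThresholds(**cfg.classifier),
        iauc_window_s=cfg.iauc_window_s,
    )


def _summaries(pm: ParameterMaps, mask: np.ndarray, dose: float) -> pd.DataFrame:
    rows = []
    for name in ("ktrans", "kep", "ve", "vb", "iauc"):
        vol = pm.maps[name]
        sel = mask & np.isfinite(vol)
        if not sel.any():
            continue
        s = histogram_moments(vol, sel, parameter=name)
        rows.append(asdict(s))
        if name == "iauc":
            rows.append(asdict(normalize_iauc(
                histogram_moments(vol, sel, parameter="iauc_normalized"), dose
            )))
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig) -> dict:
    """Run the full study analysis; returns a report dict (also written).

    Per modality: load -> convert to concentration -> input function ->
    classify/fit -> maps, per-voxel table and tumour histogram summaries.
    With two modalities the maps are compared voxel-wise on the common grid
    (Pearson + Bland-Altman per parameter, written Table-style as
    ``agreement.csv``).
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "modalities": {}}
    maps_by_mod: dict[str, ParameterMaps] = {}
    masks: dict[str, np.ndarray] = {}

    for name, mc in config.modalities.items():
        out = out_root / name.lower()
        out.mkdir(parents=True, exist_ok=True)
        try:
            series = load_dynamic_series(mc.series, mc.sidecar)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("load", f"{name}: {exc}") from exc
        acq = mc.acq()
        conc, diag = _convert(series, mc, acq, out)
        save_dynamic_series(conc, out / "concentration.nii.gz")
        ifn = _input_function(conc, mc)
        save_input_function(ifn, out / "input_function.csv")
        pm = _fit(conc, ifn, acq, config)
        save_parameter_maps(pm, out / "maps")

        tmask = (load_volume(mc.tumor_mask) > 0.5) if mc.tumor_mask else \
            np.isfinite(pm.maps["ktrans"])
        masks[name] = tmask
        summaries = _summaries(pm, tmask, acq.dose)
        summaries.to_csv(out / "histogram_summaries.csv", index=False,
                         float_format="%.8g")
        maps_by_mod[name] = pm
        counts = pm.class_counts()
        report["modalities"][name] = {
            **diag,
            "class_counts": counts,
            "n_nonconverged": pm.n_nonconverged,
            "aif_onset_s": ifn.onset_s,
            "aif_peak": ifn.peak_value,
        }
        log.info("pipeline %s done: %s", name, counts)

    if config.compare and len(maps_by_mod) >= 2:
        (name_a, pm_a), (name_b, pm_b) = list(maps_by_mod.items())[:2]
        grid = config.common_grid or pm_a.shape
        try:
            results, table = voxelwise_compare(
                pm_a, pm_b, mask=masks[name_a], grid_shape=grid
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("compare", str(exc)) from exc
        rows = [
            {"parameter": p, "r": r.r, "p": r.p_value, "bias": r.bias,
             "loa": r.loa, "n": r.n}
            for p, r in results.items()
        ]
        pd.DataFrame(rows).to_csv(out_root / "agreement.csv", index=False,
                                  float_format="%.8g")
        table.to_csv(out_root / "paired_voxels.csv", index=False,
                     float_format="%.8g")
        report["agreement"] = {
            p: {"r": r.r, "p": r.p_value, "bias": r.bias, "loa": r.loa, "n": r.n}
            for p, r in results.items()
        }
    (out_root / "run_log.json").write_text(json.dumps(report, indent=1))
    return report


# --------------------------------------------------------------------------
# Synthetic study generation
# --------------------------------------------------------------------------

def write_phantom_study(
    out_dir: str | Path,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    mri_t10_mode: str = "map",
    ct_noise_sigma: float = 0.0,
    mri_noise_sigma: float = 0.0,
) -> Path:
    """Render paired CT/MRI phantom data to disk plus a ready-to-run config.

    Writes, per modality, the raw dynamic series with its sidecar, vessel
    and tumour masks, the MRI VFA stack and ground-truth maps, and a
    ``study.yaml`` the pipeline (or the ``run`` CLI command) consumes
    directly.  Returns the path to the YAML config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = reference_phantom(rng_seed=seed)
    else:
        spec = spec.replace(rng_seed=seed)

    acq_ct = AcquisitionParams(dose=60.0)
    acq_mri = AcquisitionParams(dose=15.0)

    ct_spec = spec.replace(
        noise_model="gaussian" if ct_noise_sigma > 0 else "none",
        noise_sigma=ct_noise_sigma,
    )
    ct = render_ct_series(ct_spec, SamplingSchedule.ct_brain(), acq_ct,
                          aif_ct_preset(acq_ct.dose))
    mri_spec = spec.replace(
        noise_model="rician" if mri_noise_sigma > 0 else "none",
        noise_sigma=mri_noise_sigma,
    )
    mri_shape = aif_mri_preset(acq_mri.dose)
    mri = render_mri_series(mri_spec, SamplingSchedule.mri_flash(), acq_mri,
                            mri_shape)

    save_dynamic_series(ct.series, out / "ct_series.nii.gz", {"seed": seed})
    save_dynamic_series(mri.series, out / "mri_series.nii.gz", {"seed": seed})
    save_volume(mri.vfa_stack, out / "mri_vfa.nii.gz")
    tmask = tumor_mask(spec)
    save_volume(tmask.astype(float), out / "tumor_mask.nii.gz")
    save_volume((spec.labels == spec.artery_label).astype(float),
                out / "artery_mask.nii.gz")
    save_volume(spec.labels.astype(float), out / "labels.nii.gz")
    for key, vol in ct.truth.items():
        save_volume(vol, out / "truth" / f"{key}.nii.gz")

    cfg = {
        "out_dir": "results",
        "seed": seed,
        "modalities": {
            "CT": {
                "series": "ct_series.nii.gz",
                "tumor_mask": "tumor_mask.nii.gz",
                "vessel_mask": "artery_mask.nii.gz",
                "aif_mode": "extract",
                "acquisition": {"dose": acq_ct.dose},
            },
            "MRI": {
                "series": "mri_series.nii.gz",
                "tumor_mask": "tumor_mask.nii.gz",
                "aif_mode": "population",
                "population_aif": {
                    "amplitude": mri_shape.amplitude,
                    "onset_s": mri_shape.onset_s,
                },
                "t10_mode": mri_t10_mode,
                "vfa_stack": "mri_vfa.nii.gz",
                "vfa_angles_deg": list(acq_mri.vfa_angles_deg),
                "acquisition": {"dose": acq_mri.dose},
            },
        },
        "fit": {"fit_delay": True},
    }
    import yaml as _yaml

    cfg_path = out / "study.yaml"
    cfg_path.write_text(_yaml.safe_dump(cfg))
    return cfg_path
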