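# dcequant

Voxel-wise tracer-kinetic analysis of dynamic contrast-enhanced (DCE)
imaging, built to treat **DCE-CT and DCE-MRI with one common pipeline** so
that perfusion and permeability parameters from the two modalities can be
compared voxel by voxel. The intended users are imaging scientists studying
tumour vasculature (e.g. brain metastases before and after radiosurgery)
who want CT-validated pharmacokinetic maps from MRI, and who need every
stage of the chain — signal conversion, T1 mapping, input-function handling,
model fitting, agreement statistics — to be individually testable.

Because no patient data ships with the package, a **digital reference
phantom** generates paired CT/MRI studies from known ground-truth parameter
maps; every claim the package makes is checked by parameter recovery on
that phantom.

## The model

Tissue contrast concentration follows the modified Tofts model

```
Ct(t) = Ktrans/(1 − Hct) · [ Ca(t) ⊗ e^(−kep (t − z)) ] + Vb · Ca(t)
```

with `Ca` the (whole-blood) vascular input function, `Ktrans` (min⁻¹) the
plasma-to-interstitium transfer constant, `kep` (min⁻¹) the back-transfer
rate, `Vb` the blood volume fraction, `z` a bolus-arrival delay and `Hct`
the hematocrit (0.4 by default). The EES volume fraction is derived as
`ve = (Ktrans/(1 − Hct))/kep`.

Measured signals are converted to concentration before fitting:

* **CT** — linear: `C = ΔHU / 33` mgI/mL (baseline from precontrast frames);
* **MRI** — spoiled 3D-FLASH steady state,
  `S = S0 sin α (1 − E1)/(1 − E1 cos α)`, `E1 = exp(−TR/T1)`, inverted in
  closed form per frame, with `1/T1(t) = 1/T10 + r1 C(t)`
  (`r1 = 3.3 L·mmol⁻¹·s⁻¹` at 3 T). Precontrast `T10` comes from a
  variable-flip-angle (VFA/DESPOT1) fit at 2/10/20/30°.

Semiquantitative and agreement measures: iAUC over a 90 s post-onset
window, histogram moments (median, SD, skew, excess kurtosis), Pearson
correlation, Bland–Altman bias and 1.96·SD limits of agreement, and one-way
variance components for inter-day repeatability.

## Worked example

```python
import numpy as np
import dcequant as dq

spec = dq.reference_phantom(grid_shape=(16, 16, 6), rng_seed=0)
acq = dq.AcquisitionParams(dose=60.0)

ct = dq.render_ct_series(spec, dq.SamplingSchedule.ct_brain(), acq)
conc = dq.ct_to_concentration(ct.series, acq)
aif = dq.extract_input_function(conc, spec.labels == spec.artery_label)
print(f"AIF: onset {aif.onset_s:.1f} s, peak {aif.peak_value:.2f} mgI/mL "
      f"at {aif.peak_time_s:.1f} s")

tumor = dq.tumor_mask(spec)
pm = dq.build_parameter_maps(conc, aif, acq,
                             opts=dq.FitOptions(fit_delay=True), mask=tumor)
s = dq.histogram_moments(pm.maps["ktrans"], tumor, parameter="ktrans")
truth = np.nanmedian(ct.truth["ktrans"][tumor])
print(f"tumour Ktrans: median {s.median:.3f} min^-1 (truth {truth:.3f}), "
      f"sd {s.sd:.3f}, skew {s.skewness:.2f}, n={s.n_voxels}")
```

prints

```
AIF: onset 7.5 s, peak 12.03 mgI/mL at 15.0 s
tumour Ktrans: median 0.228 min^-1 (truth 0.229), sd 0.062, skew -1.56, n=148
```

The extracted arterial curve arrives at ~7 s and peaks at 15 s (the
analytic mode of the bolus model); the fitted tumour median Ktrans matches
the phantom's ground truth to the third decimal, and the negative skew
reflects the smooth within-tumour heterogeneity the phantom embeds.

A shell front end wraps the same stages
(`dcequant simulate | convert | fitt1 | aif | fitdce | compare | run`):

```sh
dcequant simulate --out study/ --seed 1
dcequant run --config study/study.yaml
```

which analyses both modalities and prints the per-parameter cross-modality
agreement (for the noise-free phantom, Pearson r = 1.000 for Ktrans with
bias below 1% of the mean).

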