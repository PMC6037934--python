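# Methods

## Scope and model

`dcequant` implements a single analysis chain applied to two modalities.
The kinetic core is the modified Tofts model with an explicit vascular
term,

    Ct(t) = Ktrans/(1 − Hct) · [Ca(t) ⊗ e^(−kep (t − z))] + Vb · Ca(t),

fitted per voxel to concentration-time curves. The model assumes fast
water exchange, a well-mixed blood pool, and that the vascular input is
known (measured in an artery for CT, taken from a parametric population
curve for MRI). The arrival delay `z` is implemented as a time shift of
the *whole* tissue response — kernel and vascular term together — because
shifting only the kernel would let blood arrive in the tissue before the
bolus does; the kernel-only variant remains available through
`FitOptions(delay_vascular_term=False)` since the printed form of the
equation places `(t − z)` only in the exponent.

`ve` is derived from the fitted constants as `(Ktrans/(1 − Hct))/kep`,
i.e. the impulse-response amplitude of the implemented equation divided by
`kep`; the classical `ve = Ktrans/kep` convention is available via
`FitOptions(ve_convention="classical")`. One convention is applied
globally per run.

## Signal conversion

**CT.** Concentration is the baseline-subtracted Hounsfield enhancement
divided by a calibration slope of 33 HU per mgI/mL. The baseline is the
per-voxel mean of the first `baseline_frames` frames (3 by default).

**MRI.** The spoiled 3D-FLASH steady-state magnitude equation is used in
both directions. The `exp(−TE/T2*)` factor is treated as a constant folded
into `S0`: the inversion works entirely on signal ratios in which a
constant factor cancels, and contrast-induced T2* change is not modelled.
The inversion is closed-form (solve the signal equation for `E1`, then
`T1 = −TR/ln E1`, then the relaxivity relation); voxel-frames whose signal
ratio implies `E1 ≤ 0` or `≥ 1` are flagged NaN and counted, never
clamped, because silent clamping would bias `Ktrans` downstream. Negative
concentrations produced by noise are retained through fitting (unbiased
least squares) and only clipped, if at all, at report time.

**S0 and the assumed T10.** Two S0 policies are supported and the choice
matters whenever the assumed T10 deviates from the truth:

* *baseline-inferred* (default): `S0` is computed from the baseline mean
  and the supplied T10. Under this rule an overestimated T10 inflates `S0`
  and the converted concentration **shrinks** (the effect is monotone; it
  follows from the concavity of the FLASH signal in `R1`).
* *measured* (`s0=` argument / `s0_source: vfa`): `S0` is taken from the
  equilibrium-signal map `M0` produced by the VFA fit, so only the
  relaxivity relation depends on the assumed T10 and an overestimated T10
  **raises** the converted concentration at every frame.

The fixed-T10 sensitivity analysis (see below) uses the measured-S0
policy: a platform that fits T1 maps per session has `M0` available, and
only under that policy does replacing the voxel-wise map with a too-high
constant push median Ktrans up, which is the behaviour this analysis is
designed to exhibit. The two policies agree exactly when the supplied T10
is correct.

## VFA T1 mapping

The primary estimator is the linearised DESPOT1 regression of `S/sin α` on
`S/tan α` across flip angles (2/10/20/30° at TR = 4.8 ms by default):
closed-form, fast, and exact for noise-free data. Slopes outside (0, 1)
are non-physical (`E1` must lie strictly between 0 and 1) and are masked
invalid rather than clamped. An optional per-voxel nonlinear refinement of
the FLASH equation is provided (`nonlinear_refine=True`) for users who
prefer the unweighted nonlinear estimator at low SNR; the default stays
linear because the choice of estimator is otherwise free and the linear
one is deterministic and dependency-light. Registration of the VFA frames
is assumed done upstream; the module requires co-registered input.

## Input functions

Vessel curves are spatial means over a mask (no partial-volume
correction). Bolus onset is the first frame exceeding
`baseline mean + k·SD` (k = 3) sustained for two consecutive frames, with
a tiny absolute floor so that noise-free curves trigger on any true
enhancement. The estimator is deliberately simple and configurable; on
noise-free curves it is exact, and with mask averaging it stays within one
frame at voxel SNR 20 on the staged CT schedule.

The population input is a parametric bolus: a gamma-variate first pass
(unit peak at `tp` seconds after onset, so the curve's mode is analytic),
a smaller delayed gamma-variate recirculation, and a sigmoid-gated slow
washout. Defaults give a fast peak ~8 s after arrival and a recirculation
shoulder ~20 s later. The amplitude scales linearly with injected dose
(0.2 concentration units per dose unit), which is what makes dose
normalisation of iAUC meaningful across agents. The form lives in
configuration, not code, so it can be swapped without touching the
pipeline.

## Voxel classification and fitting

Before fitting, each voxel is classified from the temporal shape of its
enhancement: *non-enhancing* (peak below `max(2% of input peak,
4·baseline SD)`), *vascular* (peak ≥ 50% of the input peak and
time-to-peak within 10 s of the input's), else *tissue-enhancing*. Only
tissue voxels are fitted. This single-pass rule set is a deliberate
stand-in for iterative temporal-dynamic-analysis classification schemes;
it preserves the mask-then-fit architecture without reproducing any
particular proprietary refinement loop. All thresholds are configurable.

Fitting is bounded trust-region least squares (`scipy.optimize
.least_squares`, TRF) over (Ktrans, kep, Vb) with optional `z`; bounds
Ktrans, kep ∈ [0, 10] min⁻¹, Vb ∈ [0, 1], z ∈ [0, 30] s keep pathological
voxels finite. A second start is tried when the first does not converge
cleanly; non-convergence is flagged, parameters retained. All-zero curves
short-circuit to a zero fit. The SSE map doubles as the fit-quality mask.

The convolution inside the model is evaluated on a uniform internal grid
(0.1 s) by an exact piecewise-linear recursion: over one step,
`y_{n+1} = e^{−k·dt} y_n + ∫ (linear segment)·e^{−k(dt−s)} ds` with the
integral in closed form, implemented as a first-order IIR filter. This is
exact for piecewise-linear inputs, O(N), and agrees with a brute-force
midpoint-Riemann quadrature at Δt = 0.01 s to ~10⁻⁵ % (measured over a
5×5 grid of rate constants). Decoupling the model grid from the
acquisition grid lets the same code handle the staged CT schedule and the
uniform MRI schedule.

iAUC integrates the concentration curve trapezoidally from bolus onset to
onset + 90 s, with exact linear interpolation of the window endpoints; the
window is measured from onset (not scan start) because injection delays
differ between modalities. A window extending past the last frame is
truncated with a warning. The "90" is configurable since the quantity is
sometimes defined over other windows or fractions.

## Agreement statistics

Conventions (all configurable only by editing one obvious place, stated
here because the field is inconsistent): sample SD (ddof = 1);
Fisher–Pearson skewness and excess kurtosis, bias-uncorrected, with the
degenerate constant sample assigned 0; Bland–Altman bias = mean(x − y) and
LoA reported as the **half-width** 1.96·SD of differences; Pearson
p-values two-sided from the t-distribution. Voxel-wise comparison
resamples both map sets to a common grid — linear interpolation for
parameter maps, nearest-neighbour for masks, voxel centres aligned over
the field of view so resampling onto the same grid is the identity — and
pairs voxels finite in both. Inter-day variance uses the one-way
random-effects moment estimators with the usual effective group size
`n0`; a negative between-day moment estimate is truncated at zero and
flagged.

## The phantom: what it emulates and what it does not

The reference phantom is a labelled volume (head ellipsoid, normal brain
with an intact-barrier trickle, a two-compartment tumour, an artery column
carrying the input and a sinus column carrying a delayed dispersed copy)
with per-label kinetics, T10, baseline HU and proton-density scale.
Tumour labels carry smooth within-label Ktrans heterogeneity (±30% by
default, from a seeded low-frequency random field) so that voxel-wise
correlation across modalities is a continuous-valued statistic rather than
a two-point comparison. Default study conditions: staged CT sampling (one
precontrast frame, 1.5 s steps to 30 s, 5 s to 120 s, 10 s to 180 s),
uniform MRI sampling (45 frames × 5.8 s with a 20 s injection delay
reflected in the bolus onset), CT dose 60 (mgI-scale amplitude 12), MRI
dose 15 (mM-scale amplitude 3), Gaussian noise in HU for CT and Rician
magnitude noise for MRI. Identical seeds give bit-identical output.

Deliberately *not* modelled: anatomy (no atlas), partial volume, motion,
B1/flip-angle inhomogeneity, T2* dynamics, water-exchange effects, and
contrast-agent differences beyond dose scale. Consequently, passing
recovery tests demonstrates the correctness and numerical behaviour of the
analysis chain — not that patient data would yield the same agreement;
in vivo the two agents differ in molecular weight and the two scans are
minutes apart, effects the phantom cannot exhibit.

## Problem sizes and numerical choices

Tests and the acceptance script run the phantom at 12–20 voxels per axis
with a few hundred tumour voxels, 25-point parameter grids with 20
replicates for noisy recovery, and 10⁵ draws for distribution-moment
checks — sizes chosen so the whole suite completes in about a minute on a
single core while keeping Monte-Carlo tolerances meaningful. The fine
model grid is 0.1 s (quadrature error far below fit noise), the
brute-force oracle uses 0.01 s, and ties/degenerate inputs are handled as
described per stage (even-length medians average the central pair; empty
masks raise rather than return silent zeros; missing voxels carry NaN,
never 0).

## Known limitations

* The voxel classifier is a single-pass stand-in; iterative
  classification-refinement schemes may assign boundary voxels differently.
* The population bolus is one parametric family; absolute iAUC across
  agents is only comparable after dose normalisation, which is exactly how
  the pipeline reports it.
* The delay `z` is fitted per voxel when enabled; there is no spatial
  regularisation of arrival times.
* LoA is reported as a half-width; multiply by two for the full interval.
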