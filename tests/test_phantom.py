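"""Phantom generator: schedules, bolus model, tissue curves, renderers."""

import numpy as np
import pytest

import dcequant as dq
from dcequant.phantom import LABEL_RIM, _gamma_variate

from conftest import riemann_tofts


class TestSchedules:
    def test_ct_schedule_matches_staged_sampling(self, ct_schedule):
        t = ct_schedule.frame_times_s
        assert t[0] == 0.0
        d = np.diff(t)
        assert np.allclose(d[(t[1:] > 0) & (t[1:] <= 30)], 1.5)
        assert np.allclose(d[(t[1:] > 30) & (t[1:] <= 120)][1:], 5.0)
        assert np.allclose(d[t[1:] > 120], 10.0)
        assert t[-1] == 180.0

    def test_mri_schedule_uniform(self, mri_schedule):
        t = mri_schedule.frame_times_s
        assert t.size == 45
        assert np.allclose(np.diff(t), 5.8)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(dq.ScheduleError):
            dq.SamplingSchedule(np.array([0.0, 2.0, 1.0]))


class TestPopulationAIF:
    def test_zero_amplitude_gives_zero_curve(self):
        shape = dq.AIFShape(amplitude=0.0)
        ifn = dq.generate_population_aif(shape, np.arange(0.0, 100.0))
        assert np.all(ifn.conc == 0.0)
        assert ifn.peak_value == 0.0

    def test_times_before_onset_are_zero(self):
        shape = dq.AIFShape(onset_s=50.0)
        ifn = dq.generate_population_aif(shape, np.arange(0.0, 49.0))
        assert np.all(ifn.conc == 0.0)

    def test_peak_at_analytic_gamma_variate_mode(self):
        # the first-pass gamma variate peaks analytically at onset + tp;
        # the recirculation/washout perturbation at that time is tiny
        shape = dq.AIFShape(amplitude=5.0)
        t = np.arange(0.0, 180.0, 0.05)
        ifn = dq.generate_population_aif(shape, t)
        assert abs(ifn.peak_time_s - shape.bolus_mode_s) <= 0.05 + 1e-12

    def test_curve_nonnegative_and_peak_consistent(self, ct_aif):
        assert np.all(ct_aif.conc >= 0.0)
        assert ct_aif.peak_value == ct_aif.conc.max()

    def test_gamma_variate_unit_peak(self):
        tau = np.array([8.0])
        assert _gamma_variate(tau, 8.0, 3.0)[0] == pytest.approx(1.0)

    def test_non_monotone_times_raise(self):
        with pytest.raises(dq.ScheduleError):
            dq.generate_population_aif(dq.AIFShape(), np.array([0.0, 2.0, 1.0]))


class TestTissueCurve:
    def test_zero_kinetics_zero_curve(self, ct_aif, ct_schedule):
        c = dq.simulate_tissue_curve(
            0.0, 0.5, 0.0, 0.4, 0.0, ct_aif, ct_schedule.frame_times_s
        )
        assert np.all(c == 0.0)

    def test_pure_blood_term_is_scaled_aif(self, ct_aif, ct_schedule):
        times = ct_schedule.frame_times_s
        c = dq.simulate_tissue_curve(0.0, 0.5, 0.05, 0.4, 0.0, ct_aif, times)
        expected = 0.05 * ct_aif.sample(times)
        np.testing.assert_allclose(c, expected, rtol=0, atol=1e-14)

    def test_matches_brute_force_riemann_convolution(self, ct_aif):
        times = np.array([15.0, 30.0, 60.0, 120.0, 180.0])
        c = dq.simulate_tissue_curve(0.2, 0.8, 0.02, 0.4, 0.0, ct_aif, times)
        brute = riemann_tofts(times, ct_aif, 0.2, 0.8, 0.02, 0.4)
        np.testing.assert_allclose(c, brute, rtol=1e-3)

    def test_hct_domain_error(self, ct_aif, ct_schedule):
        with pytest.raises(ValueError):
            dq.simulate_tissue_curve(
                0.2, 0.8, 0.02, 1.0, 0.0, ct_aif, ct_schedule.frame_times_s
            )

    def test_delay_shifts_whole_curve(self, ct_aif):
        times = np.arange(0.0, 180.0, 1.0)
        c0 = dq.simulate_tissue_curve(0.2, 0.8, 0.05, 0.4, 0.0, ct_aif, times)
        cz = dq.simulate_tissue_curve(0.2, 0.8, 0.05, 0.4, 10.0, ct_aif, times)
        np.testing.assert_allclose(cz[10:], c0[:-10], rtol=1e-10)


class TestRenderCT:
    def test_hu_rise_is_scaling_times_concentration(
        self, small_phantom, ct_schedule, acq_ct
    ):
        out = dq.render_ct_series(small_phantom, ct_schedule, acq_ct)
        rise = out.series.data - out.series.data[..., :1]
        np.testing.assert_allclose(
            rise, acq_ct.hu_scaling * out.conc_truth.data, atol=1e-9
        )

    def test_zero_kinetics_phantom_constant_over_time(self, ct_schedule, acq_ct):
        labels = np.ones((4, 4, 2), dtype=int)
        spec = dq.PhantomSpec(labels=labels, kinetics={1: dq.RegionKinetics()})
        out = dq.render_ct_series(spec, ct_schedule, acq_ct)
        assert np.ptp(out.series.data, axis=3).max() == 0.0

    def test_seeded_noise_is_reproducible(self, small_phantom, ct_schedule, acq_ct):
        spec = small_phantom.replace(noise_model="rician", noise_sigma=5.0)
        a = dq.render_ct_series(spec, ct_schedule, acq_ct)
        b = dq.render_ct_series(spec, ct_schedule, acq_ct)
        assert np.array_equal(a.series.data, b.series.data)

    def test_missing_precontrast_frame_rejected(self, small_phantom, acq_ct):
        sched = dq.SamplingSchedule(np.arange(20.0, 180.0, 5.0))
        with pytest.raises(dq.ScheduleError):
            dq.render_ct_series(small_phantom, sched, acq_ct)


class TestRenderMRI:
    def test_zero_contrast_series_equals_vfa_frame_at_dynamic_angle(
        self, mri_schedule, acq_mri
    ):
        labels = np.ones((4, 4, 2), dtype=int)
        spec = dq.PhantomSpec(
            labels=labels, kinetics={1: dq.RegionKinetics(t10_ms=1600.0)}
        )
        out = dq.render_mri_series(spec, mri_schedule, acq_mri)
        i20 = acq_mri.vfa_angles_deg.index(20.0)
        expected = np.broadcast_to(out.vfa_stack[..., i20:i20 + 1],
                                   out.series.data.shape)
        np.testing.assert_allclose(out.series.data, expected, rtol=1e-12)

    def test_signal_linear_in_s0(self, mri_schedule, acq_mri, small_phantom):
        out1 = dq.render_mri_series(small_phantom, mri_schedule, acq_mri,
                                    s0_scale=1000.0)
        out2 = dq.render_mri_series(small_phantom, mri_schedule, acq_mri,
                                    s0_scale=2000.0)
        np.testing.assert_allclose(out2.series.data, 2.0 * out1.series.data,
                                   rtol=1e-12)

    def test_signal_ratio_matches_direct_formula(self, acq_mri):
        # independent one-line evaluation of the FLASH + relaxivity equations
        tr, alpha, t10, r1, c = 4.8e-3, np.deg2rad(20.0), 1.6, 3.3, 0.5
        e1 = np.exp(-tr * (1 / t10 + r1 * c))
        e10 = np.exp(-tr / t10)
        expected = ((1 - e1) / (1 - e1 * np.cos(alpha))) / (
            (1 - e10) / (1 - e10 * np.cos(alpha))
        )
        got = dq.flash_signal(0.5, 1600.0, acq_mri) / dq.flash_signal(
            0.0, 1600.0, acq_mri
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_t10_for_label_rejected(self, mri_schedule, acq_mri):
        labels = np.ones((4, 4, 2), dtype=int)
        with pytest.raises(ValueError):
            dq.PhantomSpec(
                labels=labels, kinetics={1: dq.RegionKinetics(t10_ms=0.0)}
            )


class TestSpecValidation:
    def test_vb_out_of_range(self):
        with pytest.raises(ValueError):
            dq.PhantomSpec(
                labels=np.ones((2, 2, 2), int),
                kinetics={1: dq.RegionKinetics(vb=1.5)},
            )

    def test_implied_ve_above_one(self):
        with pytest.raises(ValueError):
            dq.PhantomSpec(
                labels=np.ones((2, 2, 2), int),
                kinetics={1: dq.RegionKinetics(ktrans=1.0, kep=0.5)},
            )

    def test_label_without_kinetics(self):
        labels = np.ones((2, 2, 2), int)
        labels[0, 0, 0] = 7
        with pytest.raises(ValueError):
            dq.PhantomSpec(labels=labels, kinetics={1: dq.RegionKinetics()})

    def test_truth_maps_deterministic_across_modalities(
        self, small_phantom, ct_schedule, mri_schedule, acq_ct, acq_mri
    ):
        ct = dq.render_ct_series(small_phantom, ct_schedule, acq_ct)
        mri = dq.render_mri_series(small_phantom, mri_schedule, acq_mri)
        np.testing.assert_array_equal(ct.truth["ktrans"], mri.truth["ktrans"])
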