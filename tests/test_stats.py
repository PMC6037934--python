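"""Histogram moments, Pearson, Bland-Altman, variance components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcequant as dq
from dcequant.kinetics import ParameterMaps
from dcequant.stats import resample_to_grid


def _maps(vols: dict):
    shape = next(iter(vols.values())).shape
    return ParameterMaps(
        maps=vols, voxel_class=np.full(shape, 2, np.int8),
        frame_times_s=np.array([0.0, 1.0]), modality="CT",
    )


class TestHistogramMoments:
    def test_constant_map(self):
        s = dq.histogram_moments(np.full((4, 4, 2), 3.0))
        assert s.sd == 0.0 and s.skewness == 0.0

    def test_small_sample_median(self):
        s = dq.histogram_moments(np.array([[[1.0, 2.0, 3.0]]]))
        assert s.median == 2.0

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(12)
        mu, sig = 0.0, 0.5
        x = rng.lognormal(mu, sig, 100_000)
        s = dq.histogram_moments(x)
        w = np.exp(sig**2)
        assert s.median == pytest.approx(np.exp(mu), rel=0.02)
        assert s.sd == pytest.approx(np.sqrt((w - 1) * np.exp(2 * mu + sig**2)),
                                     rel=0.02)
        assert s.skewness == pytest.approx((w + 2) * np.sqrt(w - 1), rel=0.10)
        kurt = w**4 + 2 * w**3 + 3 * w**2 - 6
        assert s.kurtosis == pytest.approx(kurt, rel=0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(dq.EmptyMaskError):
            dq.histogram_moments(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert dq.pearson(x, 2 * x).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert dq.pearson(x, -x + 5).r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 10)
        y = 0.4 * x + rng.uniform(0, 0.3, 10)
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert dq.pearson(x, y).r == pytest.approx(r_direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            dq.pearson(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 500), a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_symmetry_and_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r_xy = dq.pearson(x, y).r
        assert dq.pearson(y, x).r == pytest.approx(r_xy, abs=1e-12)
        assert dq.pearson(a * x + b, y).r == pytest.approx(r_xy, abs=1e-9)


class TestBlandAltman:
    def test_identical_inputs(self):
        x = np.arange(10.0)
        res = dq.bland_altman(x, x)
        assert res.bias == 0.0 and res.loa == 0.0

    def test_constant_shift(self):
        x = np.arange(10.0)
        res = dq.bland_altman(x, x - 0.05)
        assert res.bias == pytest.approx(0.05)
        assert res.loa == pytest.approx(0.0, abs=1e-12)

    def test_loa_is_1_96_sample_sd(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        res = dq.bland_altman(x, y)
        assert res.loa == 1.96 * np.std(x - y, ddof=1)

    def test_gaussian_differences_recover_mu_sigma(self):
        rng = np.random.default_rng(21)
        d = rng.normal(0.05, 0.05, 10_000)
        res = dq.bland_altman(d, np.zeros_like(d))
        assert res.bias == pytest.approx(0.05, abs=0.003)
        assert res.loa == pytest.approx(1.96 * 0.05, rel=0.03)

    def test_antisymmetric_bias(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert dq.bland_altman(x, y).bias == -dq.bland_altman(y, x).bias


class TestVoxelwiseCompare:
    def test_map_against_itself(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0.01, 0.5, (8, 8, 4))
        res, table = dq.voxelwise_compare(
            _maps({"ktrans": vol}), _maps({"ktrans": vol.copy()}),
            parameters=("ktrans",),
        )
        assert res["ktrans"].r == pytest.approx(1.0)
        assert res["ktrans"].bias == 0.0
        assert len(table) == vol.size

    def test_resampling_idempotent_on_same_grid(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(6, 5, 4))
        out = resample_to_grid(vol, (6, 5, 4))
        np.testing.assert_array_equal(out, vol)

    def test_downsampling_preserves_scale(self):
        vol = np.ones((8, 8, 4)) * 2.5
        out = resample_to_grid(vol, (4, 4, 2))
        np.testing.assert_allclose(out, 2.5)

    def test_empty_overlap_rejected(self):
        a = _maps({"ktrans": np.full((4, 4, 2), np.nan)})
        b = _maps({"ktrans": np.ones((4, 4, 2))})
        with pytest.raises(dq.EmptyMaskError):
            dq.voxelwise_compare(a, b, parameters=("ktrans",))


class TestLongitudinal:
    def _summary(self, median):
        return dq.HistogramSummary("ktrans", 10, median, 0.1, 0.0, 0.0)

    def test_percent_change(self):
        assert dq.percent_change(self._summary(0.075), self._summary(0.05)) \
            == pytest.approx(50.0)
        assert dq.percent_change(self._summary(0.05), self._summary(0.05)) == 0.0
        with pytest.raises(ValueError):
            dq.percent_change(self._summary(0.1), self._summary(0.0))

    def test_simulated_treatment_effect_recovered(self):
        base = dq.histogram_moments(np.random.default_rng(0).uniform(
            0.1, 0.3, 500))
        post = dq.HistogramSummary("ktrans", 500, base.median * 0.6,
                                   base.sd, 0.0, 0.0)
        assert dq.percent_change(post, base) == pytest.approx(-40.0)

    def test_normalize_iauc(self):
        s = dq.HistogramSummary("iauc", 10, 80.0, 12.0, 0.7, 1.2)
        assert dq.normalize_iauc(s, 1.0) == s
        n = dq.normalize_iauc(s, 2.0)
        assert n.median == 40.0 and n.sd == 6.0
        assert n.skewness == 0.7 and n.kurtosis == 1.2
        with pytest.raises(ValueError):
            dq.normalize_iauc(s, 0.0)


class TestInterdayVariance:
    def test_identical_values(self):
        res = dq.interday_variance([np.ones(5), np.ones(5), np.ones(5)])
        assert res["within_day_var"] == 0.0
        assert res["between_day_var"] == 0.0

    def test_pure_day_shifts(self):
        days = [np.full(4, m) for m in (1.0, 3.0, 5.0)]
        res = dq.interday_variance(days)
        assert res["within_day_var"] == 0.0
        assert res["between_day_var"] == pytest.approx(
            np.var([1.0, 3.0, 5.0], ddof=1)
        )

    def test_two_level_gaussian_recovery(self):
        rng = np.random.default_rng(17)
        days = [rng.normal(rng.normal(0, 1.0), 2.0, 20) for _ in range(10)]
        res = dq.interday_variance(days)
        # sampling SE of the between-day moment estimator at k=10 is ~0.6
        assert res["between_day_var"] == pytest.approx(1.0, abs=1.2)
        assert res["within_day_var"] == pytest.approx(4.0, rel=0.3)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            dq.interday_variance([np.ones(5)])
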