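"""Tests for preprocessing and the autocorrelation estimator.

The independent oracle is a naive O(N*k) double-loop implementation of the
symmetric-normalised fluctuation autocorrelator, written from the
definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btsfluct import (
    IntensityTrace,
    PhotonCarpet,
    ScanConfig,
    autocorrelate,
    bleach_correct,
    correlate_carpet,
    crop_initial,
    crop_spatial,
)
from btsfluct.correlate import multitau_lag_indices


def naive_acf(x, k):
    """Brute-force symmetric-normalised fluctuation ACF at integer lag k."""
    x = [float(v) for v in x]
    n = len(x)
    m = n - k
    num = sum(x[t] * x[t + k] for t in range(m)) / m
    mu_left = sum(x[:m]) / m
    mu_right = sum(x[k:]) / m
    return num / (mu_left * mu_right) - 1.0


def make_carpet(counts, line_hz=2000.0, dwell_us=4.0):
    counts = np.asarray(counts)
    scan = ScanConfig(
        n_pixels=counts.shape[1],
        dwell_time_us=dwell_us,
        line_frequency_hz=line_hz,
        n_lines=counts.shape[0],
    )
    return PhotonCarpet(counts, scan)


class TestCropInitial:
    def test_ten_second_crop_at_2000hz_leaves_100k_of_120k_lines(self):
        carpet = make_carpet(np.ones((120_000, 2), dtype=np.int64))
        cropped = crop_initial(carpet, 10.0)
        assert cropped.n_lines == 100_000

    def test_zero_crop_is_identity(self):
        carpet = make_carpet(np.ones((100, 2), dtype=np.int64))
        assert crop_initial(carpet, 0.0) is carpet

    def test_cropping_entire_duration_is_an_error(self):
        carpet = make_carpet(np.ones((2000, 2), dtype=np.int64))  # 1 s
        with pytest.raises(ValueError):
            crop_initial(carpet, 1.0)


class TestCropSpatial:
    def test_128_to_72_pixel_window(self):
        scan = ScanConfig(n_pixels=128, dwell_time_us=3.0, n_lines=10)
        carpet = PhotonCarpet(np.zeros((10, 128), dtype=np.int64), scan)
        out = crop_spatial(carpet, 28, 72)
        assert out.n_pixels == 72
        # downstream records keep original pixel coordinates
        assert out.pixel_indices[0] == 28
        assert out.pixel_indices[-1] == 99

    def test_keep_all_is_identity(self):
        carpet = make_carpet(np.zeros((5, 4), dtype=np.int64))
        assert crop_spatial(carpet, 0, 4) is carpet

    def test_window_out_of_range_rejected(self):
        carpet = make_carpet(np.zeros((5, 4), dtype=np.int64))
        with pytest.raises(ValueError):
            crop_spatial(carpet, 2, 3)


class TestBleachCorrect:
    def test_stationary_trace_unchanged(self):
        trace = IntensityTrace(np.tile([3.0, 5.0], 50), 0.1)
        out = bleach_correct(trace, window_s=2.0)
        np.testing.assert_allclose(out.counts, trace.counts)

    def test_two_window_rescaling_factors(self):
        """Window means 10 and 5, global 7.5: scale factors 0.75 and 1.5."""
        x = np.concatenate([np.full(10, 10.0), np.full(10, 5.0)])
        trace = IntensityTrace(x, 1.0)
        out = bleach_correct(trace, window_s=10.0)
        np.testing.assert_allclose(out.counts[:10], 7.5)
        np.testing.assert_allclose(out.counts[10:], 7.5)
        assert out.counts.mean() == pytest.approx(trace.counts.mean())

    def test_linear_decay_equalises_window_means(self):
        x = np.linspace(100.0, 50.0, 400)
        trace = IntensityTrace(x, 0.5)  # 200 s total
        out = bleach_correct(trace, window_s=16.0)  # 32-sample windows
        n_win = 32
        global_mean = x.mean()
        for start in range(0, 400 - n_win + 1, n_win):
            assert out.counts[start : start + n_win].mean() == pytest.approx(
                global_mean
            )
        assert out.counts.mean() == pytest.approx(global_mean)

    def test_zero_mean_window_left_unscaled_with_warning(self):
        x = np.concatenate([np.zeros(10), np.full(10, 4.0)])
        trace = IntensityTrace(x, 1.0)
        with pytest.warns(UserWarning, match="zero mean"):
            out = bleach_correct(trace, window_s=10.0)
        np.testing.assert_allclose(out.counts[:10], 0.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(IntensityTrace([1.0, 2.0], 1.0), window_s=10.0)


class TestAutocorrelate:
    def test_constant_trace_gives_zero_correlation(self):
        trace = IntensityTrace(np.full(64, 7.0), 1e-3)
        curve = autocorrelate(trace, scheme="linear")
        np.testing.assert_allclose(curve.g, 0.0, atol=1e-12)

    def test_alternating_trace_anticorrelates_at_lag_one(self):
        """2,0,2,0 has G(1) = -1 and G(2) = +1 (brute force on the
        4-periodic sequence)."""
        trace = IntensityTrace([2.0, 0.0, 2.0, 0.0], 1.0)
        curve = autocorrelate(trace, scheme="linear", max_lag=2)
        assert curve.g[0] == pytest.approx(-1.0, abs=1e-12)
        assert curve.g[1] == pytest.approx(1.0, abs=1e-12)

    def test_iid_poisson_trace_uncorrelated(self, rng):
        trace = IntensityTrace(rng.poisson(5.0, 50_000), 1e-3)
        curve = autocorrelate(trace, scheme="linear", max_lag=20)
        assert np.all(np.abs(curve.g) < 0.01)

    def test_first_lag_equals_sampling_interval(self):
        trace = IntensityTrace([1.0, 2.0, 1.0, 3.0, 1, 2, 1, 1], 0.25)
        curve = autocorrelate(trace, scheme="multi_tau")
        assert curve.lag_times_s[0] == pytest.approx(0.25)

    def test_linear_scheme_matches_naive_oracle(self, rng):
        x = rng.poisson(3.0, 200).astype(float)
        curve = autocorrelate(IntensityTrace(x, 1.0), scheme="linear", max_lag=40)
        expected = [naive_acf(x, k) for k in range(1, 41)]
        np.testing.assert_allclose(curve.g, expected, atol=1e-12)

    def test_multitau_matches_linear_on_shared_unbinned_lags(self, rng):
        """The first octave (lags 1..16) of the multi-tau correlator is
        computed on the raw trace and must equal the brute-force linear
        correlator to 1e-12; binned levels carry a documented small
        triangular-average bias instead."""
        x = rng.poisson(4.0, 3000).astype(float)
        mt = autocorrelate(IntensityTrace(x, 1.0), scheme="multi_tau")
        lin = autocorrelate(IntensityTrace(x, 1.0), scheme="linear", max_lag=16)
        np.testing.assert_allclose(mt.g[:16], lin.g, atol=1e-12)
        np.testing.assert_array_equal(mt.lag_times_s[:16], lin.lag_times_s)

    def test_binned_levels_approximate_linear_on_smooth_signal(self, rng):
        """Cascaded binning may only introduce the small documented bias:
        on a smooth correlated signal binned lags stay close to the exact
        linear estimator."""
        n = 4000
        phi = 0.98  # AR(1) with correlation time ~50 samples
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        x = x - x.min() + 1.0
        mt = autocorrelate(IntensityTrace(x, 1.0), scheme="multi_tau", max_lag=128)
        lin = autocorrelate(IntensityTrace(x, 1.0), scheme="linear", max_lag=128)
        shared = np.isin(lin.lag_times_s, mt.lag_times_s)
        np.testing.assert_allclose(mt.g, lin.g[shared], atol=5e-3)

    def test_scale_invariance(self, rng):
        x = rng.poisson(6.0, 500).astype(float)
        g1 = autocorrelate(IntensityTrace(x, 1.0)).g
        g2 = autocorrelate(IntensityTrace(10.0 * x, 1.0)).g
        np.testing.assert_allclose(g1, g2, rtol=1e-10)

    def test_exact_normalisation_on_ten_sample_trace(self):
        """Hand computation of the symmetric estimator on a 10-sample trace:
        lag 3 of x = (1,3,0,2,5,1,0,4,2,2):
            pairs  = 1*2+3*5+0*1+2*0+5*4+1*2+0*2 = 39,  M = 7
            mu_L   = (1+3+0+2+5+1+0)/7 = 12/7
            mu_R   = (2+5+1+0+4+2+2)/7 = 16/7
            G      = (39/7)/(12*16/49) - 1 = 39*7/(12*16) - 1
        """
        x = np.array([1, 3, 0, 2, 5, 1, 0, 4, 2, 2], dtype=float)
        curve = autocorrelate(IntensityTrace(x, 1.0), scheme="linear", max_lag=3)
        assert curve.g[2] == pytest.approx(39 * 7 / (12 * 16) - 1, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=9), min_size=12,
                        max_size=60),
        scale=st.floats(min_value=0.1, max_value=100.0, allow_nan=False),
    )
    def test_estimator_properties_on_arbitrary_traces(self, counts, scale):
        """For any non-constant, non-zero count trace: the linear estimator
        matches the brute-force definition at every lag, and G is invariant
        under positive rescaling of the trace."""
        x = np.asarray(counts, dtype=float)
        if not np.any(x) or np.all(x == x[0]):
            return
        n = x.size
        if any(x[: n - k].sum() == 0 or x[k:].sum() == 0 for k in range(1, 6)):
            return  # a zero-mean segment leaves G undefined at that lag
        curve = autocorrelate(IntensityTrace(x, 1.0), scheme="linear", max_lag=5)
        expected = [naive_acf(x, k) for k in range(1, curve.g.size + 1)]
        np.testing.assert_allclose(curve.g, expected, atol=1e-10)
        scaled = autocorrelate(
            IntensityTrace(scale * x, 1.0), scheme="linear", max_lag=5
        )
        np.testing.assert_allclose(scaled.g, curve.g, rtol=1e-8, atol=1e-10)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            autocorrelate(IntensityTrace(np.zeros(32), 1.0))

    def test_multitau_lag_grid_structure(self):
        lags = multitau_lag_indices(10_000, m=16)
        assert list(lags[:16]) == list(range(1, 17))
        # second octave: 18..32 step 2
        assert list(lags[16:24]) == [18, 20, 22, 24, 26, 28, 30, 32]
        assert lags[-1] <= 5000


class TestCorrelateCarpet:
    def test_one_curve_per_pixel(self, sim_carpet):
        curves = correlate_carpet(sim_carpet, crop_seconds=1.0)
        assert len(curves) == sim_carpet.n_pixels
        assert [c.pixel_index for c in curves] == list(range(50))

    def test_all_zero_pixel_skipped_with_warning(self, caplog):
        counts = np.ones((400, 3), dtype=np.int64)
        counts[:, 1] = 0
        carpet = make_carpet(counts)
        with caplog.at_level("WARNING", logger="btsfluct.correlate"):
            curves = correlate_carpet(carpet)
        assert [c.pixel_index for c in curves] == [0, 2]
        assert any("all-zero" in r.message for r in caplog.records)
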