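"""Cross-recurrence machinery checked against naive brute-force oracles."""

import numpy as np
import pytest

from dyadsync.recurrence import (
    EmbeddingParams,
    calibrate_radius,
    cross_recurrence,
    diagonal_profile,
    embed,
    estimate_delay,
    estimate_dimension,
    run_crqa,
)


def naive_recurrence_matrix(pa, pb, radius):
    """Double-loop oracle for the recurrence matrix."""
    pa = np.atleast_2d(pa.T).T
    pb = np.atleast_2d(pb.T).T
    m = np.zeros((len(pa), len(pb)), dtype=bool)
    for i in range(len(pa)):
        for j in range(len(pb)):
            m[i, j] = np.linalg.norm(pa[i] - pb[j]) <= radius
    return m


def naive_ami(x, k, bins=16):
    """Histogram mutual information at lag k, computed independently."""
    a, b = x[:-k], x[k:]
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px, py = p.sum(1), p.sum(0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi


class TestDelay:
    def test_sine_delay_matches_bruteforce_ami_minimum(self):
        s = np.sin(2 * np.pi * np.arange(2000) / 40.0)
        d = estimate_delay(s, max_delay=20)
        ami = [naive_ami(s, k) for k in range(1, 21)]
        first_min = next(
            k + 1
            for k in range(19)
            if ami[k] < ami[k + 1] and (k == 0 or ami[k] < ami[k - 1])
        )
        assert d == first_min
        # the AMI valley of a period-40 sine sits around the quarter period
        assert 4 <= d <= 15

    def test_white_noise_delay_is_immediate(self):
        x = np.random.default_rng(4).normal(size=4000)
        assert estimate_delay(x, max_delay=20) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_delay(np.ones(500), 10)


class TestDimension:
    def test_noiseless_sine_needs_two_dimensions(self):
        s = np.sin(2 * np.pi * np.arange(2000) / 40.0)
        assert estimate_dimension(s, delay=10) == 2

    def test_white_noise_hits_the_cap(self):
        x = np.random.default_rng(3).normal(size=3000)
        with pytest.warns(UserWarning, match="never settled"):
            assert estimate_dimension(x, delay=1, max_dim=6) == 6

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_dimension(np.ones(500), 1)


class TestEmbed:
    @pytest.mark.parametrize(
        "series,delay,dim,expected",
        [
            ([1, 2, 3, 4], 1, 2, [[1, 2], [2, 3], [3, 4]]),
            ([1, 2, 3, 4], 1, 1, [[1], [2], [3], [4]]),
            ([1, 2, 3, 4], 2, 2, [[1, 3], [2, 4]]),
        ],
    )
    def test_examples(self, series, delay, dim, expected):
        np.testing.assert_array_equal(embed(np.array(series, float), delay, dim), expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed(np.arange(4.0), delay=2, dimension=3)


class TestRadiusCalibration:
    def test_five_percent_quantile_recounts_correctly(self):
        rng = np.random.default_rng(10)
        pa, pb = rng.normal(size=500), rng.normal(size=500)
        r = calibrate_radius(pa, pb, 0.05)
        # brute-force recount over all 500^2 distances
        d = np.abs(pa[:, None] - pb[None, :])
        achieved = np.mean(d <= r)
        assert 0.045 <= achieved <= 0.055

    def test_full_recurrence_at_target_one(self):
        rng = np.random.default_rng(1)
        pa, pb = rng.normal(size=50), rng.normal(size=50)
        r = calibrate_radius(pa, pb, 1.0)
        assert np.all(np.abs(pa[:, None] - pb[None, :]) <= r)

    def test_zero_target_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="target_rr"):
            calibrate_radius(rng.normal(size=10), rng.normal(size=10), 0.0)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_radius(np.ones(10), np.ones(10), 0.05)

    def test_achieved_rr_close_to_target_on_random_inputs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pa = rng.normal(size=(300, 3))
            pb = rng.normal(size=(300, 3))
            r = calibrate_radius(pa, pb, 0.05)
            rr = cross_recurrence(pa, pb, r).mean()
            assert abs(rr - 0.05) <= 0.005


class TestCrossRecurrence:
    def test_identical_points_tiny_radius_gives_identity_diagonal(self):
        p = np.random.default_rng(0).normal(size=(30, 2))
        m = cross_recurrence(p, p, 1e-12)
        assert np.all(np.diag(m))

    def test_huge_radius_gives_full_matrix(self):
        rng = np.random.default_rng(1)
        m = cross_recurrence(rng.normal(size=(20, 2)), rng.normal(size=(20, 2)), 1e6)
        assert m.all()

    def test_matches_bruteforce_exactly(self):
        rng = np.random.default_rng(2)
        pa, pb = rng.normal(size=(60, 2)), rng.normal(size=(60, 2))
        m = cross_recurrence(pa, pb, 0.5)
        np.testing.assert_array_equal(m, naive_recurrence_matrix(pa, pb, 0.5))

    def test_rr_monotone_in_radius(self):
        rng = np.random.default_rng(3)
        pa, pb = rng.normal(size=(100, 2)), rng.normal(size=(100, 2))
        rrs = [cross_recurrence(pa, pb, r).mean() for r in np.linspace(0.05, 3.0, 12)]
        assert np.all(np.diff(rrs) >= 0)


class TestDiagonalProfile:
    def test_window_is_101_lags(self):
        m = np.ones((200, 200), dtype=bool)
        lags, rr, npts = diagonal_profile(m, 50)
        assert len(lags) == len(rr) == 101
        assert lags[0] == -50 and lags[-1] == 50
        np.testing.assert_array_equal(rr, 1.0)

    def test_transpose_reverses_profile(self):
        rng = np.random.default_rng(5)
        m = rng.random((120, 120)) < 0.2
        _, rr_ab, _ = diagonal_profile(m, 30)
        _, rr_ba, _ = diagonal_profile(m.T, 30)
        np.testing.assert_allclose(rr_ab, rr_ba[::-1])

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            diagonal_profile(np.ones((40, 40)), 50)


class TestRunCRQA:
    def test_self_comparison_has_full_lag_zero_recurrence(self):
        x = np.random.default_rng(6).normal(size=600)
        x = np.convolve(x, np.ones(5) / 5, mode="same")
        res = run_crqa(x, x.copy(), target_rr=0.05, max_lag=20)
        assert res.drp[20] == 1.0

    def test_shifted_copy_peaks_at_positive_lag(self):
        # b[t] = a[t-10]: A leads B by 10 samples, so the DRP peak must sit
        # at lag +10 under the "positive lag = A leads" convention
        rng = np.random.default_rng(7)
        raw = np.convolve(rng.normal(size=700), np.ones(7) / 7, mode="same")
        a, b = raw[10:660], raw[0:650]
        res = run_crqa(a, b, params=EmbeddingParams(1, 1, 0.05), max_lag=20)
        assert res.lags[np.argmax(res.drp)] == 10

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            run_crqa(np.arange(100.0), np.arange(99.0))

    @pytest.mark.parametrize("seed,n,delay,dim", [(0, 120, 1, 2), (1, 200, 3, 2), (2, 150, 2, 3)])
    def test_streaming_drp_matches_bruteforce_oracle(self, seed, n, delay, dim):
        rng = np.random.default_rng(seed)
        a = np.convolve(rng.normal(size=n), np.ones(4) / 4, mode="same")
        b = np.convolve(rng.normal(size=n), np.ones(4) / 4, mode="same")
        res = run_crqa(a, b, target_rr=0.05, max_lag=30, max_delay=delay, max_dim=dim)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        pa = embed(za, res.params.delay, res.params.dimension)
        pb = embed(zb, res.params.delay, res.params.dimension)
        m = naive_recurrence_matrix(pa, pb, res.params.radius)
        assert res.rr == np.mean(m)
        lags, rr, npts = diagonal_profile(m, 30)
        np.testing.assert_array_equal(res.drp, rr)
        np.testing.assert_array_equal(res.n_points, npts)

    def test_recorded_params_reproduce_result(self):
        rng = np.random.default_rng(9)
        a = np.convolve(rng.normal(size=500), np.ones(5) / 5, mode="same")
        b = np.convolve(rng.normal(size=500), np.ones(5) / 5, mode="same")
        first = run_crqa(a, b, max_lag=25)
        again = run_crqa(a, b, params=first.params, max_lag=25)
        np.testing.assert_array_equal(first.drp, again.drp)
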