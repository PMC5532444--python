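"""Preprocessing chain: zero-phase Butterworth filtering, decimation,
Euclidean magnitude, derivatives, burst detection and trimming."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

from dyadsync.core import AccelTrace, MovementSeries
from dyadsync.design import CouplingSpec, StudyDesign
from dyadsync.preprocess import (
    antialias_filter,
    derivatives,
    downsample,
    euclidean_acceleration,
    find_dyad_cutoff,
    inclusion_filter,
    preprocess_conversation,
    preprocess_trace,
    smooth,
    trim_and_truncate,
)
from dyadsync.simulate import simulate_dyad, simulate_study


def _sine_trace(freq_hz, duration_s=20.0, rate=250.0):
    t = np.arange(int(duration_s * rate)) / rate
    s = np.sin(2 * np.pi * freq_hz * t)
    return AccelTrace(t, s, np.zeros_like(s), np.zeros_like(s), sample_rate_hz=rate)


class TestAntialiasFilter:
    def test_passband_preserved(self):
        out = antialias_filter(_sine_trace(1.0))
        # compare away from the edges
        sl = slice(500, -500)
        assert np.abs(out.x[sl]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuated(self):
        out = antialias_filter(_sine_trace(20.0))
        assert np.abs(out.x[1000:-1000]).max() < 0.01

    def test_constant_unchanged(self):
        tr = _sine_trace(1.0)
        tr.x[:] = 2.5
        out = antialias_filter(tr)
        np.testing.assert_allclose(out.x, 2.5, atol=1e-8)

    def test_zero_phase(self):
        rng = np.random.default_rng(0)
        tr = _sine_trace(1.0)
        tr.x = sp_signal.lfilter([1], [1, -0.95], rng.normal(size=len(tr)))
        out = antialias_filter(tr)
        xc = sp_signal.correlate(out.x, tr.x, mode="full")
        lag = np.argmax(xc) - (len(tr) - 1)
        assert lag == 0

    def test_short_series_rejected(self):
        t = np.arange(5) / 250.0
        tr = AccelTrace(t, t, t, t, sample_rate_hz=250.0)
        with pytest.raises(ValueError, match="too short"):
            antialias_filter(tr)


class TestDownsample:
    def test_count_and_timestamps(self):
        tr = _sine_trace(1.0, duration_s=60.0)
        out = downsample(tr)
        assert len(out) == 600
        np.testing.assert_array_equal(out.t, tr.t[::25])
        assert out.sample_rate_hz == 10.0

    def test_non_integer_ratio_rejected(self):
        t = np.arange(1000) / 249.0
        tr = AccelTrace(t, t, t, t, sample_rate_hz=249.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(tr)


@pytest.mark.parametrize(
    "xyz,expected",
    [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), np.sqrt(3))],
)
def test_euclidean_acceleration(xyz, expected):
    t = np.arange(10) / 10.0
    tr = AccelTrace(
        t, np.full(10, xyz[0]), np.full(10, xyz[1]), np.full(10, xyz[2]),
        sample_rate_hz=10.0,
    )
    np.testing.assert_allclose(euclidean_acceleration(tr).a, expected)


class TestSmooth:
    def test_constant_unchanged(self):
        s = MovementSeries(np.arange(100) / 10.0, np.full(100, 1.3))
        np.testing.assert_allclose(smooth(s).a, 1.3, atol=1e-9)

    def test_high_frequency_variance_reduced(self):
        a = np.tile([0.0, 1.0], 200)
        s = MovementSeries(np.arange(400) / 10.0, a)
        assert smooth(s).a.var() < a.var()

    def test_slow_component_preserved(self):
        t = np.arange(600) / 10.0
        s = MovementSeries(t, np.sin(2 * np.pi * 0.5 * t))
        out = smooth(s)
        assert np.abs(out.a[100:-100]).max() == pytest.approx(1.0, rel=0.05)


class TestDerivatives:
    def test_linear_ramp(self):
        t = np.arange(100) / 10.0
        jerk, jounce = derivatives(MovementSeries(t, t.copy()))
        np.testing.assert_allclose(jerk, 1.0, atol=1e-9)
        np.testing.assert_allclose(jounce[1:-1], 0.0, atol=1e-9)

    def test_quadratic(self):
        t = np.arange(100) / 10.0
        _, jounce = derivatives(MovementSeries(t, t**2))
        # one-sided endpoint estimates of jerk bias the two outermost
        # jounce values; the central-difference interior is exact
        np.testing.assert_allclose(jounce[2:-2], 2.0, atol=1e-8)

    def test_planted_bump_curvature_peaks_at_center(self):
        # a Gaussian bump's second derivative has its global magnitude
        # maximum at the bump center
        t = np.arange(1000) / 10.0
        center = 500
        a = np.exp(-0.5 * ((t - t[center]) / 1.0) ** 2)
        _, jounce = derivatives(MovementSeries(t, a))
        assert abs(int(np.argmax(np.abs(jounce))) - center) <= 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            derivatives(MovementSeries(np.array([0.0, 0.1]), np.array([0.0, 1.0])))


@pytest.fixture(scope="module")
def planted_pair():
    design = StudyDesign(conversation_duration_s=300.0, seed=61)
    return simulate_dyad(
        design, CouplingSpec(effect_map={}), "d01", "noise",
        ("affiliative", "argumentative"), np.random.default_rng(61),
        burst_times_s={"affiliative": (80.0, 95.0), "argumentative": (70.0, 70.0)},
    )


class TestDyadCutoff:
    def test_dyad_cutoff_is_later_burst(self, planted_pair):
        ta, tb = planted_pair["affiliative"]
        sa, sb = preprocess_trace(ta), preprocess_trace(tb)
        cut = find_dyad_cutoff(sa, sb)
        assert cut.jounce_a == pytest.approx(80.0, abs=1.0)
        assert cut.jounce_b == pytest.approx(95.0, abs=1.0)
        assert cut.dyad == pytest.approx(95.0, abs=1.0)
        assert 60.0 <= cut.dyad <= 120.0

    def test_identical_series_give_equal_cutoffs(self, planted_pair):
        ta, _ = planted_pair["argumentative"]
        sa = preprocess_trace(ta)
        cut = find_dyad_cutoff(sa, sa)
        assert cut.jounce_a == cut.jounce_b == cut.dyad

    def test_window_beyond_series_rejected(self):
        t = np.arange(500) / 10.0  # 50 s only
        s = MovementSeries(t, np.ones_like(t))
        with pytest.raises(ValueError, match="covers only"):
            find_dyad_cutoff(s, s)

    def test_jerk_and_jounce_cutoffs_correlate(self):
        from dyadsync.design import DropoutSpec

        study = simulate_study(
            StudyDesign(n_dyads=21, n_noise=9, conversation_duration_s=180.0, seed=62),
            dropout=DropoutSpec(hazard_per_s=0.0),
        )
        jerk, jounce = [], []
        for dyad in study.dyads:
            for conv in dyad.conversations:
                sa = preprocess_trace(conv.trace_a)
                sb = preprocess_trace(conv.trace_b)
                cut = find_dyad_cutoff(sa, sb)
                jerk.append(max(cut.jerk_a, cut.jerk_b))
                jounce.append(max(cut.jounce_a, cut.jounce_b))
        r = np.corrcoef(jerk, jounce)[0, 1]
        assert r > 0.5


class TestTrimAndInclusion:
    def test_trim_equalizes_lengths(self):
        t = np.arange(4800) / 10.0
        sa = MovementSeries(t, np.ones_like(t))
        sb = MovementSeries(t[:4500], np.ones(4500))
        ta, tb = trim_and_truncate(sa, sb, 0.0)
        assert len(ta) == len(tb) == 4500

    def test_trim_starts_at_cutoff(self):
        t = np.arange(2000) / 10.0
        s = MovementSeries(t, np.ones_like(t))
        ta, tb = trim_and_truncate(s, s.copy(), 95.0)
        assert ta.t[0] >= 95.0
        assert ta.trimmed and tb.trimmed

    def test_series_ending_before_cutoff_rejected(self):
        t = np.arange(500) / 10.0  # ends at 50 s
        s = MovementSeries(t, np.ones_like(t))
        with pytest.raises(ValueError, match="ends before"):
            trim_and_truncate(s, s.copy(), 95.0)

    def test_inclusion_rule(self):
        rows = []
        for dyad, durations in {
            "ok": [480, 480, 480, 480],
            "short": [180, 480, 480, 480],  # one 3-min trace sinks the dyad
            "boundary": [270, 480, 480, 480],  # inclusive bound
        }.items():
            rows += [{"dyad": dyad, "duration_s": d} for d in durations]
        kept = inclusion_filter(pd.DataFrame(rows))
        assert kept == {"ok", "boundary"}


def test_pipeline_rate_and_alignment(coupled_dyad):
    ta, tb = coupled_dyad["affiliative"]
    sa, sb, cut = preprocess_conversation(ta, tb)
    assert sa.rate_hz == sb.rate_hz == 10.0
    assert len(sa) == len(sb)
    np.testing.assert_allclose(np.diff(sa.t), 0.1, atol=1e-9)
    assert sa.filtered and sa.smoothed and sa.trimmed
    assert 60.0 <= cut.dyad <= 120.0
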