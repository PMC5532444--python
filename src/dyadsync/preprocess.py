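"""Raw trace -> trimmed 10 Hz scalar acceleration series.

The preparation pipeline, in order:

1. zero-phase 4th-order Butterworth anti-alias filter (5 Hz cutoff, the
   Nyquist frequency of the target rate);
2. decimation to 10 Hz (integer ratios only);
3. 3-D Euclidean magnitude, giving one acceleration value per sample;
4. zero-phase 2nd-order Butterworth smoothing filter (2 Hz cutoff);
5. jerk/jounce derivative analysis to locate the calibration burst,
   dyad-level cutoff = the *later* of the two participants' jounce peaks
   in the 60-120 s window;
6. trimming both participants to the cutoff and truncating to the
   shorter of the two lengths.

Zero phase is achieved by forward-backward application (filtfilt), which
doubles the effective order; edges are handled by odd reflection padding.
The Butterworth cutoff frequencies are package defaults chosen to retain
nod/shake dynamics while removing sensor jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Set, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .core import AccelTrace, MovementSeries

__all__ = [
    "antialias_filter",
    "downsample",
    "euclidean_acceleration",
    "smooth",
    "derivatives",
    "find_dyad_cutoff",
    "trim_and_truncate",
    "inclusion_filter",
    "preprocess_trace",
    "preprocess_conversation",
    "CutoffResult",
    "MIN_KEEP_S",
]

MIN_KEEP_S = 270.0  # 4.5 min inclusion bound, inclusive


def _filtfilt(x: np.ndarray, order: int, cutoff_hz: float, rate_hz: float) -> np.ndarray:
    if len(x) < 3 * (order + 1):
        raise ValueError(
            f"series of length {len(x)} too short for zero-phase order-{order} filtering"
        )
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sp_signal.sosfiltfilt(sos, x)


def antialias_filter(
    trace: AccelTrace, cutoff_hz: float = 5.0, order: int = 4
) -> AccelTrace:
    """Zero-phase low-pass Butterworth anti-alias filter on each axis.

    The default 5 Hz cutoff is the Nyquist frequency of the 10 Hz target
    rate, so energy that would alias on decimation is removed.
    """
    out = trace.copy()
    out.x = _filtfilt(trace.x, order, cutoff_hz, trace.sample_rate_hz)
    out.y = _filtfilt(trace.y, order, cutoff_hz, trace.sample_rate_hz)
    out.z = _filtfilt(trace.z, order, cutoff_hz, trace.sample_rate_hz)
    return out


def downsample(trace: AccelTrace, target_hz: float = 10.0) -> AccelTrace:
    """Keep every k-th sample, k = original rate / target rate.

    The anti-alias filter must already have been applied.  Non-integer
    decimation ratios are rejected rather than resampled.
    """
    ratio = trace.sample_rate_hz / target_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"sample rate {trace.sample_rate_hz} Hz is not an integer multiple "
            f"of target {target_hz} Hz"
        )
    return AccelTrace(
        trace.t[::k], trace.x[::k], trace.y[::k], trace.z[::k],
        participant=trace.participant, conversation=trace.conversation,
        sample_rate_hz=target_hz,
    )


def euclidean_acceleration(trace: AccelTrace) -> MovementSeries:
    """Collapse the three axes to a single scalar: a = sqrt(x^2+y^2+z^2)."""
    a = np.sqrt(trace.x**2 + trace.y**2 + trace.z**2)
    return MovementSeries(
        trace.t, a, rate_hz=trace.sample_rate_hz,
        participant=trace.participant, conversation=trace.conversation,
        filtered=True,
    )


def smooth(series: MovementSeries, cutoff_hz: float = 2.0, order: int = 2) -> MovementSeries:
    """Zero-phase 2nd-order Butterworth smoothing of the scalar signal."""
    out = series.copy()
    out.a = _filtfilt(series.a, order, cutoff_hz, series.rate_hz)
    out.smoothed = True
    return out


def derivatives(series: MovementSeries) -> Tuple[np.ndarray, np.ndarray]:
    """Jerk (da/dt) and jounce (d2a/dt2) by central finite differences.

    Endpoints use one-sided differences; outputs have the same length as
    the input.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    jerk = np.gradient(series.a, series.t)
    jounce = np.gradient(jerk, series.t)
    return jerk, jounce


@dataclass
class CutoffResult:
    """Per-participant burst-detection candidates and the dyad cutoff.

    All times in seconds from conversation start.  The dyad cutoff is
    the later (more conservative) of the two jounce cutoffs.
    """

    jerk_a: float
    jerk_b: float
    jounce_a: float
    jounce_b: float
    dyad: float


def _argmax_latest(values: np.ndarray) -> int:
    """Argmax with ties broken toward the latest index."""
    return len(values) - 1 - int(np.argmax(values[::-1]))


def _burst_time(series: MovementSeries, deriv: np.ndarray, window: Tuple[float, float]) -> float:
    mask = (series.t >= window[0]) & (series.t <= window[1])
    if not np.any(mask):
        raise ValueError("calibration window not covered by series")
    idx = np.flatnonzero(mask)
    j = _argmax_latest(np.abs(deriv[idx]))
    return float(series.t[idx[j]])


def find_dyad_cutoff(
    series_a: MovementSeries,
    series_b: MovementSeries,
    window: Tuple[float, float] = (60.0, 120.0),
) -> CutoffResult:
    """Locate the calibration burst and pick the dyad-level cutoff.

    For each participant the cutoff candidate is the time of largest
    absolute jounce (and, for diagnostics, jerk) within ``window``; the
    dyad cutoff is the later of the two jounce candidates and is applied
    identically to both participants.
    """
    for s in (series_a, series_b):
        if s.duration_s < window[1]:
            raise ValueError(
                f"series {s.participant!r} covers only {s.duration_s:.1f} s; "
                f"the calibration window extends to {window[1]} s"
            )
    jerk_a, jounce_a = derivatives(series_a)
    jerk_b, jounce_b = derivatives(series_b)
    res = CutoffResult(
        jerk_a=_burst_time(series_a, jerk_a, window),
        jerk_b=_burst_time(series_b, jerk_b, window),
        jounce_a=_burst_time(series_a, jounce_a, window),
        jounce_b=_burst_time(series_b, jounce_b, window),
        dyad=0.0,
    )
    res.dyad = max(res.jounce_a, res.jounce_b)
    return res


def trim_and_truncate(
    series_a: MovementSeries, series_b: MovementSeries, cutoff_s: float
) -> Tuple[MovementSeries, MovementSeries]:
    """Drop everything before ``cutoff_s`` and equalize lengths.

    Both series start at the cutoff; the pair is truncated to the
    shorter of the two post-cutoff lengths.
    """
    out = []
    for s in (series_a, series_b):
        mask = s.t >= cutoff_s
        if not np.any(mask):
            raise ValueError(
                f"series {s.participant!r} ends before the cutoff at {cutoff_s:.1f} s"
            )
        c = s.copy()
        c.t, c.a = s.t[mask], s.a[mask]
        c.trimmed = True
        out.append(c)
    n = min(len(out[0]), len(out[1]))
    if n < 1:
        raise ValueError("no samples remain after trimming")
    for c in out:
        c.t, c.a = c.t[:n], c.a[:n]
    return out[0], out[1]


def inclusion_filter(
    durations: pd.DataFrame, min_keep_s: float = MIN_KEEP_S
) -> Set[str]:
    """Apply the 4.5-minute inclusion rule.

    ``durations`` must have columns ``dyad`` and ``duration_s`` with one
    row per participant-conversation trace (four per dyad).  A dyad is
    retained iff *every* trace lasts at least ``min_keep_s`` seconds
    (inclusive bound).
    """
    ok = durations.groupby("dyad")["duration_s"].apply(
        lambda d: bool((d >= min_keep_s).all())
    )
    return set(ok[ok].index)


def preprocess_trace(
    trace: AccelTrace,
    target_hz: float = 10.0,
    antialias_cutoff_hz: float = 5.0,
    smooth_cutoff_hz: float = 2.0,
) -> MovementSeries:
    """Full single-trace pipeline: anti-alias -> downsample -> magnitude -> smooth."""
    filtered = antialias_filter(trace, cutoff_hz=antialias_cutoff_hz)
    down = downsample(filtered, target_hz=target_hz)
    mag = euclidean_acceleration(down)
    return smooth(mag, cutoff_hz=smooth_cutoff_hz)


def preprocess_conversation(
    trace_a: AccelTrace,
    trace_b: AccelTrace,
    target_hz: float = 10.0,
    window: Tuple[float, float] = (60.0, 120.0),
) -> Tuple[MovementSeries, MovementSeries, CutoffResult]:
    """Preprocess both participants of a conversation and trim at the
    dyad-level jounce cutoff.  Returns the aligned pair and the cutoffs."""
    sa = preprocess_trace(trace_a, target_hz=target_hz)
    sb = preprocess_trace(trace_b, target_hz=target_hz)
    cut = find_dyad_cutoff(sa, sb, window=window)
    ta, tb = trim_and_truncate(sa, sb, cut.dyad)
    assert len(ta) == len(tb), "truncation must equalize lengths"
    return ta, tb, cut
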