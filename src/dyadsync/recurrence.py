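"""Continuous cross-recurrence quantification.

Given two equal-length scalar movement series, the pipeline is:

1. z-score each series (so one radius is comparable across dyads);
2. time-delay embedding, with the delay chosen as the first local
   minimum of average mutual information (AMI) and the dimension by the
   false-nearest-neighbors (FNN) criterion -- each estimated per series,
   with the pairwise maxima shared by both members of the dyad;
3. radius calibration: the radius is the empirical quantile of all
   pairwise cross-distances at which the overall recurrence rate (RR)
   equals a target (5% by default);
4. the diagonal recurrence profile (DRP): RR per diagonal for lags
   -50..+50 samples (+-5 s at 10 Hz).

Sign convention: a positive lag d means participant A at time t is
compared with participant B at time t + d, i.e. A leads B.

The full recurrence matrix is never required: per-diagonal counts are
computed by streaming over lags, and the overall RR directly from the
cross-distance distribution.  No Theiler window is applied -- the two
series are different systems, so no line of identity exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import MovementSeries

__all__ = [
    "EmbeddingParams",
    "RecurrenceResult",
    "estimate_delay",
    "estimate_dimension",
    "embed",
    "calibrate_radius",
    "cross_recurrence",
    "diagonal_profile",
    "run_crqa",
]

ArrayLike = Union[np.ndarray, MovementSeries]


def _as_array(series: ArrayLike) -> np.ndarray:
    if isinstance(series, MovementSeries):
        return np.asarray(series.a, dtype=float)
    return np.asarray(series, dtype=float)


@dataclass(frozen=True)
class EmbeddingParams:
    """Phase-space reconstruction parameters for one dyad-conversation."""

    delay: int
    dimension: int
    radius: float
    rescale: str = "zscore"

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class RecurrenceResult:
    """Overall RR plus the diagonal recurrence profile for one pair."""

    rr: float
    lags: np.ndarray
    drp: np.ndarray
    n_points: np.ndarray  # pairs entering each diagonal
    params: EmbeddingParams


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    cxy, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = cxy / cxy.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def estimate_delay(series: ArrayLike, max_delay: int = 40, bins: int = 16) -> int:
    """Embedding delay: first local minimum of AMI over lags 1..max_delay.

    Falls back to the first zero crossing of the autocorrelation, then
    to ``max_delay`` with a warning.  A constant series has no usable
    structure and raises.
    """
    x = _as_array(series)
    if np.ptp(x) == 0:
        raise ValueError("cannot estimate a delay for a constant series")
    max_delay = int(min(max_delay, max(len(x) // 10, 2)))
    ami = np.array(
        [_mutual_information(x[:-k], x[k:], bins=bins) for k in range(1, max_delay + 1)]
    )
    for i in range(len(ami) - 1):
        left_ok = i == 0 or ami[i] < ami[i - 1]
        if left_ok and ami[i] < ami[i + 1]:
            return i + 1
    # fallback: first autocorrelation zero crossing
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    for k in range(1, max_delay + 1):
        if np.dot(xc[:-k], xc[k:]) / denom <= 0:
            return k
    warnings.warn(
        "no AMI minimum or autocorrelation zero crossing found; using max_delay",
        stacklevel=2,
    )
    return max_delay


def embed(series: ArrayLike, delay: int, dimension: int) -> np.ndarray:
    """Time-delay embedding: point i = (s_i, s_{i+d}, ..., s_{i+(m-1)d}).

    Returns an (N - (m-1)*d, m) array.
    """
    x = _as_array(series)
    span = (dimension - 1) * delay
    n = len(x) - span
    if n < 1:
        raise ValueError(
            f"series of length {len(x)} too short for dimension {dimension}, delay {delay}"
        )
    return np.column_stack([x[i * delay : i * delay + n] for i in range(dimension)])


def estimate_dimension(
    series: ArrayLike,
    delay: int,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
    threshold: float = 0.1,
) -> int:
    """Embedding dimension by the false-nearest-neighbors criterion.

    Returns the smallest m whose FNN fraction falls below ``threshold``;
    candidate dimensions the series is too short to test are skipped.
    If no m settles (e.g. white noise), ``max_dim`` is returned with a
    warning.
    """
    x = _as_array(series)
    if np.ptp(x) == 0:
        raise ValueError("cannot estimate a dimension for a constant series")
    sd = float(np.std(x))
    for m in range(1, max_dim + 1):
        n_next = len(x) - m * delay  # points available at dimension m+1
        if n_next < 10:
            continue
        pts = embed(x, delay, m)[:n_next]
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=2)
        nn, d_m = idx[:, 1], dist[:, 1]
        extra = x[np.arange(n_next) + m * delay] - x[nn + m * delay]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(extra) / d_m
        d_next = np.sqrt(d_m**2 + extra**2)
        # neighbors at (numerically) zero distance: false iff they separate
        tiny = 1e-10 * sd
        false = np.where(
            d_m > tiny, (ratio > rtol) | (d_next / sd > atol), np.abs(extra) > tiny
        )
        if float(np.mean(false)) < threshold:
            return m
    warnings.warn(
        "FNN fraction never settled below threshold; using max_dim", stacklevel=2
    )
    return max_dim


def _ensure_2d(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    return p


def calibrate_radius(
    points_a: np.ndarray,
    points_b: np.ndarray,
    target_rr: float = 0.05,
) -> float:
    """Radius at which the overall cross-recurrence rate hits ``target_rr``.

    The radius is the (linearly interpolated) ``target_rr`` quantile of
    all pairwise Euclidean cross-distances, which by construction puts
    the achieved RR within half a percentage point of the target on any
    non-degenerate input.
    """
    if not 0 < target_rr <= 1:
        raise ValueError("target_rr must be in (0, 1]")
    pa, pb = _ensure_2d(points_a), _ensure_2d(points_b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("point sets must be non-empty")
    d = cdist(pa, pb)
    if d.max() == d.min():
        raise ValueError(
            "degenerate geometry: all cross-distances identical, RR jumps 0 -> 1"
        )
    if target_rr == 1.0:
        return float(d.max())
    return float(np.quantile(d, target_rr))


def cross_recurrence(
    points_a: np.ndarray, points_b: np.ndarray, radius: float
) -> np.ndarray:
    """Explicit boolean cross-recurrence matrix.

    Entry (i, j) is True iff ||a_i - b_j|| <= radius.  Intended for
    moderate sizes; the streaming DRP path never materializes it.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pa, pb = _ensure_2d(points_a), _ensure_2d(points_b)
    return cdist(pa, pb) <= radius


def diagonal_profile(matrix: np.ndarray, max_lag: int = 50) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DRP from an explicit recurrence matrix.

    Returns (lags, rr, n_points) with lags -max_lag..+max_lag; lag d
    averages entries (i, i+d), so positive lags mean the row series
    leads the column series.
    """
    m = np.asarray(matrix)
    if m.shape[0] <= max_lag or m.shape[1] <= max_lag:
        raise ValueError(
            f"matrix of shape {m.shape} too small for max_lag {max_lag}"
        )
    lags = np.arange(-max_lag, max_lag + 1)
    rr = np.empty(len(lags))
    npts = np.empty(len(lags), dtype=int)
    for i, d in enumerate(lags):
        diag = np.diagonal(m, offset=d)
        rr[i] = float(np.mean(diag))
        npts[i] = len(diag)
    return lags, rr, npts


def _streaming_drp(
    points_a: np.ndarray, points_b: np.ndarray, radius: float, max_lag: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-diagonal recurrence counts without the full matrix."""
    pa, pb = _ensure_2d(points_a), _ensure_2d(points_b)
    n = min(len(pa), len(pb))
    if n <= max_lag:
        raise ValueError(f"only {n} embedded points; need more than max_lag={max_lag}")
    lags = np.arange(-max_lag, max_lag + 1)
    rr = np.empty(len(lags))
    npts = np.empty(len(lags), dtype=int)
    for i, d in enumerate(lags):
        # pairs (i, i+d): valid i in [max(0,-d), min(len(pa), len(pb)-d))
        start = max(0, -d)
        stop = min(len(pa), len(pb) - d)
        da = pa[start:stop]
        db = pb[start + d : stop + d]
        dist = np.sqrt(np.sum((da - db) ** 2, axis=1))
        rr[i] = float(np.mean(dist <= radius))
        npts[i] = len(dist)
    return lags, rr, npts


def run_crqa(
    series_a: ArrayLike,
    series_b: ArrayLike,
    params: Optional[EmbeddingParams] = None,
    target_rr: float = 0.05,
    max_lag: int = 50,
    max_delay: int = 40,
    max_dim: int = 10,
    rescale: bool = True,
    delay: Optional[int] = None,
    dimension: Optional[int] = None,
) -> RecurrenceResult:
    """Full continuous-CRQA pass for one pair of equal-length series.

    With ``params`` omitted, the delay and dimension are estimated per
    series (AMI / FNN) and the per-pair maxima shared — or pinned via
    ``delay``/``dimension`` — then the radius calibrated to
    ``target_rr``; with ``params`` given (e.g. a parent dyad's
    parameters for a surrogate pair) everything is reused as-is.
    """
    xa, xb = _as_array(series_a), _as_array(series_b)
    if len(xa) != len(xb):
        raise ValueError("series must have equal length (run trim_and_truncate first)")
    if rescale:
        if np.std(xa) == 0 or np.std(xb) == 0:
            raise ValueError("cannot z-score a constant series")
        xa = (xa - xa.mean()) / xa.std()
        xb = (xb - xb.mean()) / xb.std()
    if params is None:
        if delay is None:
            delay = max(estimate_delay(xa, max_delay), estimate_delay(xb, max_delay))
        if dimension is None:
            dimension = max(
                estimate_dimension(xa, delay, max_dim),
                estimate_dimension(xb, delay, max_dim),
            )
        pa, pb = embed(xa, delay, dimension), embed(xb, delay, dimension)
        radius = calibrate_radius(pa, pb, target_rr)
        params = EmbeddingParams(delay, dimension, radius)
    else:
        pa, pb = embed(xa, params.delay, params.dimension), embed(
            xb, params.delay, params.dimension
        )
        radius = params.radius
    d = cdist(pa, pb)
    rr = float(np.mean(d <= radius))
    del d
    lags, drp, npts = _streaming_drp(pa, pb, radius, max_lag)
    return RecurrenceResult(rr=rr, lags=lags, drp=drp, n_points=npts, params=params)
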