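"""Chance baselines for the recurrence analysis.

Two surrogate constructions:

* **Fourier phase randomization** (primary): keeps the parent's discrete
  Fourier amplitude spectrum (hence autocorrelation) exactly, draws new
  phases uniformly with conjugate symmetry enforced.  Both members of a
  dyad are randomized with independent phases, destroying cross-series
  alignment while each margin keeps its own dynamics.
* **Sample-wise shuffle** (supplementary): permutes the samples, keeping
  the exact value multiset but destroying autocorrelation.

Surrogates are generated on the trimmed 10 Hz scalar series (after
preprocessing, before embedding) and pushed through CRQA with the parent
dyad's stored delay/dimension/radius -- no re-calibration, so surrogate
overall RR is allowed to drift from the 5% target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import MovementSeries
from .recurrence import EmbeddingParams, run_crqa

__all__ = [
    "phase_randomize",
    "sample_shuffle",
    "SurrogateEnsemble",
    "make_ensemble",
    "build_baseline_drps",
]


def phase_randomize(series, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate with the parent's amplitude spectrum.

    The DC component is untouched (mean preserved exactly); for even
    lengths the Nyquist bin stays real with a random sign.
    """
    x = np.asarray(series.a if isinstance(series, MovementSeries) else series, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples to phase-randomize")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    n = len(x)
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    phases = np.zeros_like(amp)
    if n % 2 == 0:
        # bins 1..n/2-1 free; Nyquist bin must stay real
        phases[1:-1] = rng.uniform(0, 2 * np.pi, len(amp) - 2)
        phases[-1] = np.pi * rng.integers(2)  # random sign
    else:
        phases[1:] = rng.uniform(0, 2 * np.pi, len(amp) - 1)
    phases[0] = 0.0 if spec[0].real >= 0 else np.pi
    return np.fft.irfft(amp * np.exp(1j * phases), n)


def sample_shuffle(series, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of the samples (exact multiset preserved)."""
    x = np.asarray(series.a if isinstance(series, MovementSeries) else series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to shuffle")
    return rng.permutation(x)


_METHODS = {"phase_randomization": phase_randomize, "sample_shuffle": sample_shuffle}


@dataclass
class SurrogateEnsemble:
    """A set of surrogates for one parent series."""

    parent_id: str
    method: str
    seed: int
    surrogates: List[np.ndarray] = field(default_factory=list)

    @property
    def n_surrogates(self) -> int:
        return len(self.surrogates)


def make_ensemble(
    series,
    method: str = "phase_randomization",
    n_surrogates: int = 10,
    seed: int = 0,
    parent_id: str = "",
) -> SurrogateEnsemble:
    """Generate ``n_surrogates`` surrogates, one independent seeded RNG
    stream per surrogate."""
    if method not in _METHODS:
        raise ValueError(f"unknown surrogate method {method!r}")
    fn = _METHODS[method]
    streams = np.random.SeedSequence(seed).spawn(n_surrogates)
    ens = SurrogateEnsemble(parent_id, method, seed)
    for s in streams:
        ens.surrogates.append(fn(series, np.random.default_rng(s)))
    return ens


def build_baseline_drps(
    pairs: Iterable[Mapping],
    method: str = "phase_randomization",
    n_surrogates: int = 10,
    rng: Optional[np.random.Generator] = None,
    max_lag: int = 50,
) -> pd.DataFrame:
    """Surrogate DRPs for every dyad-conversation, in long format.

    Each element of ``pairs`` must be a mapping with keys ``dyad``,
    ``conversation`` (conversation number), ``conv_type``, ``task``,
    ``series_a``, ``series_b`` and ``params`` (the parent pair's fitted
    :class:`EmbeddingParams`).  Both members are randomized with
    independent phases and re-analyzed with the parent's parameters.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if method not in _METHODS:
        raise ValueError(f"unknown surrogate method {method!r}")
    fn = _METHODS[method]
    rows = []
    for rec in pairs:
        params = rec.get("params")
        if params is None:
            raise ValueError(
                f"missing embedding parameters for dyad {rec.get('dyad')!r} "
                f"conversation {rec.get('conversation')!r}"
            )
        xa = np.asarray(
            rec["series_a"].a if isinstance(rec["series_a"], MovementSeries) else rec["series_a"],
            dtype=float,
        )
        xb = np.asarray(
            rec["series_b"].a if isinstance(rec["series_b"], MovementSeries) else rec["series_b"],
            dtype=float,
        )
        for sid in range(1, n_surrogates + 1):
            sa = fn(xa, rng)
            sb = fn(xb, rng)
            res = run_crqa(sa, sb, params=params, max_lag=max_lag)
            rows.append(
                pd.DataFrame(
                    {
                        "dyad": rec["dyad"],
                        "conversation": rec["conversation"],
                        "conv_type": rec["conv_type"],
                        "task": rec["task"],
                        "source": "surrogate",
                        "surrogate_id": sid,
                        "lag": res.lags,
                        "rr": res.drp,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["dyad", "conversation", "conv_type", "task", "source", "surrogate_id", "lag", "rr"]
        )
    return pd.concat(rows, ignore_index=True)
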