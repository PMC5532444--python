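"""Core in-memory containers shared across the pipeline stages.

An :class:`AccelTrace` is a raw, regularly sampled 3-axis accelerometer
record for one participant in one conversation.  A :class:`MovementSeries`
is the derived scalar acceleration signal after filtering and
downsampling.  Both are thin dataclasses around numpy arrays; all heavy
lifting lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["AccelTrace", "MovementSeries"]


@dataclass
class AccelTrace:
    """Raw timestamped 3-axis accelerometer stream.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing and regular.
    x, y, z : ndarray
        Acceleration along the three sensor axes, in sensor units.
    participant : str
        Participant identifier (e.g. ``"d03a"``).
    conversation : str
        Conversation identifier (e.g. ``"d03-affiliative"``).
    sample_rate_hz : float
        Nominal sampling rate.  Checked against ``t`` on construction.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    participant: str = ""
    conversation: str = ""
    sample_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("t, x, y, z must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(
                    f"timestamps must be strictly increasing (violation at row {i + 1})"
                )
            period = 1.0 / self.sample_rate_hz
            if np.max(np.abs(dt - period)) > 0.5 * period:
                raise ValueError(
                    "irregular sampling: max timestamp jitter exceeds half a sample period"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Recorded duration in seconds (sample count over nominal rate)."""
        return len(self.t) / self.sample_rate_hz

    def copy(self) -> "AccelTrace":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(), z=self.z.copy()
        )


@dataclass
class MovementSeries:
    """Scalar acceleration magnitude series, nominally at 10 Hz.

    ``filtered``/``smoothed``/``trimmed`` are provenance flags recording
    which preprocessing stages the series has passed through.
    """

    t: np.ndarray
    a: np.ndarray
    rate_hz: float = 10.0
    participant: str = ""
    conversation: str = ""
    filtered: bool = False
    smoothed: bool = False
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if len(self.t) != len(self.a):
            raise ValueError("t and a must have equal length")

    def __len__(self) -> int:
        return len(self.a)

    @property
    def duration_s(self) -> float:
        return len(self.a) / self.rate_hz

    def copy(self) -> "MovementSeries":
        return replace(self, t=self.t.copy(), a=self.a.copy())
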