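"""Synthetic dyadic accelerometer and stimulus-stream generator.

The generator produces per-participant 3-axis accelerometer traces with
the statistical structure the downstream analysis assumes:

* each participant's movement is an AR(1) oscillatory drive gated by a
  two-state (moving/still) bout process evolving at a 10 Hz control rate;
* the partner's bout state cross-excites (in-phase coupling) or
  cross-inhibits (turn-taking coupling) the bout switch probabilities;
* the scalar drive is projected onto three axes with a fixed random
  orientation per participant, plus white sensor noise;
* a high-jounce calibration burst (rapid nodding/shaking) is planted
  60-120 s into each recording, marking the conversation onset;
* an exponential server-dropout process censors traces to prefixes;
* a 1 Hz red/blue stimulus stream with P(red) = 0.1.

Traces are emitted at the full 250 Hz measurement rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import uniform_filter1d

from .core import AccelTrace
from .design import (
    CONVERSATION_TYPES,
    CouplingSpec,
    DropoutSpec,
    StudyDesign,
    TASK_CONDITIONS,
)

__all__ = [
    "simulate_stimulus_stream",
    "plant_calibration_burst",
    "apply_dropout",
    "simulate_dyad",
    "simulate_study",
    "SimulatedConversation",
    "SimulatedDyad",
    "SimulatedStudy",
]

_CONTROL_HZ = 10.0  # rate at which the bout processes evolve


def simulate_stimulus_stream(
    duration_s: float, rng: np.random.Generator, p_red: float = 0.1
) -> np.ndarray:
    """Draw one screen color per second: ``"red"`` with probability
    ``p_red`` (default 0.1), else ``"blue"``.  Draws are independent."""
    n = int(duration_s)
    if n < 1:
        raise ValueError("duration_s must be >= 1")
    red = rng.random(n) < p_red
    return np.where(red, "red", "blue")


def _coupled_bout_states(
    n_steps: int,
    p_on: float,
    p_off: float,
    inphase_gain: float,
    turntaking_gain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the two participants' moving/still bout processes jointly.

    Returns a (2, n_steps) boolean array (True = moving).  The partner's
    state at the previous step multiplies the switch probabilities:
    in-phase coupling raises p_on / lowers p_off while the partner moves,
    turn-taking coupling does the opposite.
    """
    gi = 1.0 + inphase_gain
    gt = 1.0 + turntaking_gain
    states = np.empty((2, n_steps), dtype=bool)
    cur = rng.random(2) < 0.5
    u = rng.random((2, n_steps))
    for t in range(n_steps):
        nxt = cur.copy()
        for i in (0, 1):
            partner_moving = cur[1 - i]
            if partner_moving:
                on = p_on * gi / gt
                off = p_off * gt / gi
            else:
                on = p_on * gt / gi
                off = p_off * gi / gt
            if cur[i]:
                if u[i, t] < min(off, 0.6):
                    nxt[i] = False
            else:
                if u[i, t] < min(on, 0.6):
                    nxt[i] = True
        cur = nxt
        states[:, t] = cur
    return states


def _ar1_drive(n: int, rate_hz: float, timescale_s: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean AR(1) process with unit marginal variance."""
    phi = float(np.exp(-1.0 / (rate_hz * timescale_s)))
    eps = rng.normal(0.0, np.sqrt(1.0 - phi**2), n)
    return sp_signal.lfilter([1.0], [1.0, -phi], eps)


def _conversation_pair(
    design: StudyDesign,
    coupling: CouplingSpec,
    conv_type: str,
    task: str,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate the two participants' raw (n, 3) axis signals for one
    conversation, without the calibration burst."""
    rate = design.sample_rate_hz
    n = int(round(design.conversation_duration_s * rate))
    k = int(round(rate / _CONTROL_HZ))
    n_steps = int(np.ceil(n / k))
    g_in, g_tt = coupling.gains_for(conv_type, task)
    bouts = _coupled_bout_states(
        n_steps, coupling.bout_p_on, coupling.bout_p_off, g_in, g_tt, rng
    )
    out = []
    for i in (0, 1):
        env = np.repeat(bouts[i].astype(float), k)[:n]
        # ~0.5 s moving-average keeps the envelope from stepping
        env = uniform_filter1d(env, size=max(1, int(0.5 * rate)))
        amp = coupling.still_amplitude + (1.0 - coupling.still_amplitude) * env
        drive = _ar1_drive(n, rate, coupling.drive_timescale_s, rng)
        scalar = coupling.base_amplitude * amp * drive
        axis_dir = rng.normal(size=3)
        axis_dir /= np.linalg.norm(axis_dir)
        xyz = scalar[:, None] * axis_dir[None, :]
        xyz = xyz + rng.normal(0.0, coupling.noise_sd, (n, 3))
        out.append(xyz)
    return out[0], out[1]


def plant_calibration_burst(
    trace: AccelTrace,
    t_burst_s: float,
    rng: np.random.Generator,
    amplitude: float = 12.0,
    duration_s: float = 2.0,
    freq_hz: float = 3.0,
) -> AccelTrace:
    """Superimpose a brief bout of high-jounce head movement.

    The burst is an ``amplitude``-scaled ``freq_hz`` oscillation under a
    Hann window of ``duration_s`` seconds centered at ``t_burst_s``,
    projected onto a random axis direction.  ``t_burst_s`` must lie in
    the 60-120 s calibration window, and the amplitude must be positive:
    a requested burst may not silently be a no-op.
    """
    if not 60.0 <= t_burst_s <= 120.0:
        raise ValueError(
            f"t_burst_s={t_burst_s} outside the 60-120 s calibration window"
        )
    if amplitude <= 0:
        raise ValueError("burst amplitude must be > 0 (a burst-free trace was requested)")
    rate = trace.sample_rate_hz
    if trace.duration_s < t_burst_s + duration_s / 2:
        raise ValueError("trace too short to contain the requested burst")
    n_b = int(round(duration_s * rate))
    tt = np.arange(n_b) / rate
    burst = amplitude * np.sin(2 * np.pi * freq_hz * tt) * np.hanning(n_b)
    i0 = int(round((t_burst_s - duration_s / 2) * rate))
    i0 = max(i0, 0)
    axis_dir = rng.normal(size=3)
    axis_dir /= np.linalg.norm(axis_dir)
    out = trace.copy()
    seg = slice(i0, i0 + n_b)
    out.x[seg] += axis_dir[0] * burst[: len(out.x[seg])]
    out.y[seg] += axis_dir[1] * burst[: len(out.y[seg])]
    out.z[seg] += axis_dir[2] * burst[: len(out.z[seg])]
    return out


def apply_dropout(
    traces: Sequence[AccelTrace],
    spec: DropoutSpec,
    rng: np.random.Generator,
) -> Tuple[List[AccelTrace], bool]:
    """Censor each trace to a prefix at an exponential disconnect time.

    Returns the censored traces and an inclusion flag that is True iff
    every censored trace retains at least ``spec.min_keep_s`` seconds.
    With hazard 0 the traces are returned unchanged.
    """
    censored: List[AccelTrace] = []
    included = True
    for tr in traces:
        if spec.hazard_per_s > 0:
            t_disc = rng.exponential(1.0 / spec.hazard_per_s)
        else:
            t_disc = np.inf
        if t_disc < tr.duration_s:
            n_keep = max(int(np.floor(t_disc * tr.sample_rate_hz)), 0)
            tr = AccelTrace(
                tr.t[:n_keep], tr.x[:n_keep], tr.y[:n_keep], tr.z[:n_keep],
                participant=tr.participant, conversation=tr.conversation,
                sample_rate_hz=tr.sample_rate_hz,
            )
        censored.append(tr)
        if tr.duration_s < spec.min_keep_s:
            included = False
    return censored, included


def simulate_dyad(
    design: StudyDesign,
    coupling: CouplingSpec,
    dyad_id: str,
    task: str,
    conv_order: Sequence[str],
    rng: np.random.Generator,
    plant_bursts: bool = True,
    burst_times_s: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Dict[str, Tuple[AccelTrace, AccelTrace]]:
    """Simulate both conversations of one dyad.

    Returns ``{conv_type: (trace_a, trace_b)}``.  Both traces of a
    conversation share start time and nominal length; each carries a
    calibration burst at an independent time in the 60-120 s window
    (overridable per conversation via ``burst_times_s``).
    """
    if design.conversation_duration_s < 180.0:
        raise ValueError(
            "conversation_duration_s must be >= 180 s to contain the "
            "60-120 s calibration window and usable conversation data"
        )
    if task not in TASK_CONDITIONS:
        raise ValueError(f"unknown task condition {task!r}")
    if sorted(conv_order) != sorted(CONVERSATION_TYPES):
        raise ValueError("conv_order must contain each conversation type exactly once")
    rate = design.sample_rate_hz
    n = int(round(design.conversation_duration_s * rate))
    t = np.arange(n) / rate
    result: Dict[str, Tuple[AccelTrace, AccelTrace]] = {}
    for conv_type in conv_order:
        xyz_a, xyz_b = _conversation_pair(design, coupling, conv_type, task, rng)
        pair = []
        for pid, xyz in zip(("a", "b"), (xyz_a, xyz_b)):
            tr = AccelTrace(
                t, xyz[:, 0], xyz[:, 1], xyz[:, 2],
                participant=f"{dyad_id}{pid}",
                conversation=f"{dyad_id}-{conv_type}",
                sample_rate_hz=rate,
            )
            if plant_bursts:
                if burst_times_s is not None and conv_type in burst_times_s:
                    tb = burst_times_s[conv_type][0 if pid == "a" else 1]
                else:
                    tb = rng.uniform(65.0, 115.0)
                tr = plant_calibration_burst(tr, tb, rng)
            pair.append(tr)
        result[conv_type] = (pair[0], pair[1])
    return result


@dataclass
class SimulatedConversation:
    conv_type: str
    number: int  # 1 or 2 (order within the dyad)
    trace_a: AccelTrace
    trace_b: AccelTrace


@dataclass
class SimulatedDyad:
    dyad_id: str
    task: str
    conversations: List[SimulatedConversation]
    included: bool = True


@dataclass
class SimulatedStudy:
    design: StudyDesign
    coupling: CouplingSpec
    dropout: DropoutSpec
    dyads: List[SimulatedDyad] = field(default_factory=list)

    @property
    def included_dyads(self) -> List[SimulatedDyad]:
        return [d for d in self.dyads if d.included]


def simulate_study(
    design: StudyDesign,
    coupling: Optional[CouplingSpec] = None,
    dropout: Optional[DropoutSpec] = None,
) -> SimulatedStudy:
    """Simulate a full study: task assignment, counterbalanced
    conversation order, coupled movement, bursts, and dropout censoring.

    Reproducible: the entire study derives from ``design.seed``.
    """
    coupling = coupling if coupling is not None else CouplingSpec()
    dropout = dropout if dropout is not None else DropoutSpec()
    root = np.random.SeedSequence(design.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    # task assignment: n_noise dyads noise, rest dual-task, random order
    tasks = np.array(
        ["noise"] * design.n_noise + ["dual-task"] * (design.n_dyads - design.n_noise)
    )
    assign_rng.shuffle(tasks)
    # counterbalanced conversation order: alternate, random starting order
    start_aff_first = bool(assign_rng.integers(2))
    study = SimulatedStudy(design, coupling, dropout)
    dyad_seeds = root.spawn(design.n_dyads)
    for i in range(design.n_dyads):
        rng = np.random.default_rng(dyad_seeds[i])
        dyad_id = f"d{i + 1:02d}"
        aff_first = start_aff_first if i % 2 == 0 else not start_aff_first
        order = ("affiliative", "argumentative") if aff_first else ("argumentative", "affiliative")
        traces = simulate_dyad(design, coupling, dyad_id, tasks[i], order, rng)
        flat = []
        for conv_type in order:
            flat.extend(traces[conv_type])
        censored, included = apply_dropout(flat, dropout, rng)
        convs = [
            SimulatedConversation(order[j], j + 1, censored[2 * j], censored[2 * j + 1])
            for j in range(2)
        ]
        study.dyads.append(SimulatedDyad(dyad_id, tasks[i], convs, included))
    return study
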