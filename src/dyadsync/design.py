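"""Study-design and generator-parameter specifications.

The defaults mirror the design of the dyadic conversation study the
generator emulates: 21 dyads, each holding one affiliative and one
argumentative ~8-minute conversation (order counterbalanced), with a
between-dyads task manipulation (9 "noise" dyads, 12 "dual-task" dyads),
head movement sampled at 250 Hz, and a calibration burst of rapid head
movement 60-120 s into each recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

CONVERSATION_TYPES: Tuple[str, str] = ("affiliative", "argumentative")
TASK_CONDITIONS: Tuple[str, str] = ("dual-task", "noise")

#: condition -> (inphase_gain, turntaking_gain).  Affiliative conversations
#: carry in-phase coupling (simultaneous movement); argumentative
#: conversations carry turn-taking coupling (alternating movement), more
#: strongly under dual-task than noise.  These shapes give the generator the
#: ability to produce both a lag-0 synchrony peak and a U-shaped profile.
DEFAULT_EFFECT_MAP: Dict[Tuple[str, str], Tuple[float, float]] = {
    ("affiliative", "dual-task"): (1.5, 0.0),
    ("affiliative", "noise"): (1.5, 0.0),
    ("argumentative", "dual-task"): (0.0, 2.5),
    ("argumentative", "noise"): (0.0, 0.8),
}


@dataclass(frozen=True)
class StudyDesign:
    """Top-level layout of a simulated study.

    ``n_noise`` dyads receive the noise task condition; the remainder the
    dual-task condition.  Conversation-type order is counterbalanced to
    within one dyad across the study.
    """

    n_dyads: int = 21
    n_noise: int = 9
    conversation_duration_s: float = 480.0
    sample_rate_hz: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if not 0 <= self.n_noise <= self.n_dyads:
            raise ValueError("n_noise must be between 0 and n_dyads")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of the dyadic movement generator.

    Each participant's movement is a latent AR(1) "drive" gated by a
    two-state (moving/still) bout process; the partner's bout state
    modulates the switch probabilities.  ``inphase_gain`` pushes the two
    bout processes toward simultaneous movement, ``turntaking_gain``
    toward alternation.  ``effect_map`` assigns per-condition gains,
    overriding the scalar gains when the condition is present.
    """

    base_amplitude: float = 1.0
    drive_timescale_s: float = 0.3     # AR(1) correlation time of the drive
    bout_p_on: float = 0.04            # per 10 Hz control step: still -> moving
    bout_p_off: float = 0.04           # per 10 Hz control step: moving -> still
    still_amplitude: float = 0.15      # residual postural movement when "still"
    inphase_gain: float = 0.0
    turntaking_gain: float = 0.0
    noise_sd: float = 0.05             # white sensor noise per axis
    effect_map: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_MAP)
    )

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        gains = [self.inphase_gain, self.turntaking_gain]
        gains += [g for pair in self.effect_map.values() for g in pair]
        if any(g < 0 for g in gains):
            raise ValueError("coupling gains must be >= 0")

    def gains_for(self, conv_type: str, task: str) -> Tuple[float, float]:
        """(inphase, turntaking) gains for a condition cell."""
        return self.effect_map.get((conv_type, task), (self.inphase_gain, self.turntaking_gain))


@dataclass(frozen=True)
class DropoutSpec:
    """Server-disconnect censoring.

    A disconnect hazard per second per participant-conversation; once
    disconnected, no further samples are recorded (the retained data are
    an unbroken prefix).  A dyad is included only if all four
    participant-conversation traces retain at least ``min_keep_s``
    seconds.  The default hazard makes the expected dyad exclusion
    fraction about one half, the loss rate the generator emulates.
    """

    hazard_per_s: float = 6.4e-4
    min_keep_s: float = 270.0

    def __post_init__(self) -> None:
        if not 0 <= self.hazard_per_s < 1:
            raise ValueError("hazard_per_s must be in [0, 1)")
        if self.min_keep_s < 0:
            raise ValueError("min_keep_s must be >= 0")
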