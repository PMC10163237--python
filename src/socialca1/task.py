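"""Task structure: trial timing, epochs, and the trial-table schema.

A trial runs as follows (times in seconds from the start of imaging in the
trial).  Imaging starts ``pre_open_imaging_s`` before the interaction window
opens (epoch ``O``), the window takes ``opening_motion_s`` to open fully,
licks have no consequence during the grace period until the response window
starts (epoch ``R``), and the window closes ``window_open_s`` after ``O``
(epoch ``C``).  Imaging continues ``post_close_imaging_s`` past ``C``.

Trial tables are plain :class:`pandas.DataFrame` objects with the columns in
:data:`TRIAL_COLUMNS`; ``lick_times`` holds a list of lick times per trial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

#: reward category labels
REWARD = "reward"
NO_REWARD = "no-reward"

#: trial outcome labels
HIT = "hit"
MISS = "miss"
FA = "FA"
CR = "CR"

#: required columns of a trial table
TRIAL_COLUMNS = [
    "trial_idx",
    "day",
    "stimulus",
    "category",
    "t_open",
    "t_open_complete",
    "t_response",
    "t_close",
    "lick_times",
    "outcome",
    "rewarded",
]


@dataclass(frozen=True)
class TaskSpec:
    """Timing and stimulus layout of a Go-NoGo discrimination session.

    Parameters
    ----------
    stimuli
        Stimulus labels (2 for the two-mouse task, 4 for the four-mouse task).
    category_map
        Mapping of each stimulus to ``"reward"`` or ``"no-reward"``.
    grace_s
        Delay between window opening and the start of the response window
        (0.8-1.3 s; 1.3 s default).
    """

    stimuli: tuple[str, ...] = ("A", "B")
    category_map: dict[str, str] = field(
        default_factory=lambda: {"A": REWARD, "B": NO_REWARD}
    )
    grace_s: float = 1.3
    window_open_s: float = 4.0
    opening_motion_s: float = 0.4
    iti_s: float = 12.0
    frame_rate_hz: float = 30.0
    pre_open_imaging_s: float = 1.2
    post_close_imaging_s: float = 0.8

    def __post_init__(self) -> None:
        if not 0.8 <= self.grace_s <= 1.3:
            raise ValueError(f"grace_s must be in [0.8, 1.3], got {self.grace_s}")
        if set(self.category_map) != set(self.stimuli):
            raise ValueError("category_map must cover exactly the stimuli")
        bad = {c for c in self.category_map.values() if c not in (REWARD, NO_REWARD)}
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    # -- epoch times (s from trial start) -----------------------------------
    @property
    def t_open(self) -> float:
        return self.pre_open_imaging_s

    @property
    def t_open_complete(self) -> float:
        return self.t_open + self.opening_motion_s

    @property
    def t_response(self) -> float:
        return self.t_open + self.grace_s

    @property
    def t_close(self) -> float:
        return self.t_open + self.window_open_s

    @property
    def trial_duration_s(self) -> float:
        return self.pre_open_imaging_s + self.window_open_s + self.post_close_imaging_s

    @property
    def n_frames(self) -> int:
        """Frames imaged per trial (180 at defaults: 6 s at 30 Hz)."""
        return int(round(self.frame_rate_hz * self.trial_duration_s))

    def epoch_frames(self) -> dict[str, int]:
        """0-based frame indices of the four epoch markers within a trial."""
        fr = self.frame_rate_hz
        return {
            "open": int(round(self.t_open * fr)),
            "open_complete": int(round(self.t_open_complete * fr)),
            "response": int(round(self.t_response * fr)),
            "close": int(round(self.t_close * fr)),
        }

    def reversed_map(self) -> dict[str, str]:
        """The category map with reward and no-reward swapped."""
        flip = {REWARD: NO_REWARD, NO_REWARD: REWARD}
        return {s: flip[c] for s, c in self.category_map.items()}


def child_seed(seed: int, *labels: str | int) -> np.random.SeedSequence:
    """Derive a reproducible child seed from a global seed and a label path.

    The splitting rule: the global seed is extended with the CRC32 of each
    label, and the whole tuple seeds a :class:`numpy.random.SeedSequence`.
    Any stage of the pipeline can thus be re-run in isolation given the
    global seed and its label path.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        entropy.append(zlib.crc32(str(lab).encode()) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy)


def rng_for(seed: int, *labels: str | int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for one named pipeline stage."""
    return np.random.default_rng(child_seed(seed, *labels))
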