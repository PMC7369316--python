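"""Experimental design constants and epoch definitions.

The main experiment shows videos of seven observed manipulative actions
(OMAs) in four visual formats — the crossing of actor posture
(standing / sitting) with camera viewpoint (lateral / frontal).  Each
OMA x format combination is further varied by actor identity and target
object, and every individual video is shown three times, giving
7 x 4 x 2 x 2 x 3 = 336 trials per session (12 trials per OMA x format
cell).  A control session shows nine natural dynamic scenes, ten trials
each, with per-video motion and contrast covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EXEMPLARS: tuple[str, ...] = (
    "drag", "drop", "grasp", "push", "roll", "rotate", "squeeze",
)
POSTURES: tuple[str, str] = ("standing", "sitting")
VIEWPOINTS: tuple[str, str] = ("lateral", "frontal")
ACTORS: tuple[str, str] = ("m", "f")
OBJECTS: tuple[str, str] = ("a", "b")

#: Canonical format order F1..F4: posture x viewpoint.
FORMATS: tuple[str, ...] = (
    "stand_lateral", "sit_lateral", "stand_frontal", "sit_frontal",
)
FORMAT_FACTORS: dict[str, tuple[str, str]] = {
    "stand_lateral": ("standing", "lateral"),
    "sit_lateral": ("sitting", "lateral"),
    "stand_frontal": ("standing", "frontal"),
    "sit_frontal": ("sitting", "frontal"),
}

N_EXEMPLARS = len(EXEMPLARS)
N_FORMATS = len(FORMATS)


@dataclass(frozen=True)
class EpochWindows:
    """Half-open analysis windows in seconds relative to video onset."""

    baseline: tuple[float, float] = (-0.5, 0.0)
    epoch1: tuple[float, float] = (0.0, 0.3)
    epoch2: tuple[float, float] = (0.3, 1.5)
    #: Control-experiment video epoch; the first 500 ms are dropped so that
    #: gaze re-centring cannot contaminate the response estimate.
    control_video: tuple[float, float] = (0.5, 3.0)

    def main(self) -> dict[str, tuple[float, float]]:
        return {
            "baseline": self.baseline,
            "epoch1": self.epoch1,
            "epoch2": self.epoch2,
        }

    def control(self) -> dict[str, tuple[float, float]]:
        return {"baseline": self.baseline, "video": self.control_video}


@dataclass(frozen=True)
class DesignSpec:
    """Trial-structure constants for one recording session."""

    n_exemplars: int = 7
    n_formats: int = 4
    n_actors: int = 2
    n_objects: int = 2
    n_repetitions: int = 3
    baseline_window_s: float = 0.5
    video_duration_s: float = 2.6
    n_control_videos: int = 9
    n_control_trials_per_video: int = 10
    control_video_duration_s: float = 3.5
    epochs: EpochWindows = field(default_factory=EpochWindows)

    def __post_init__(self) -> None:
        if self.n_exemplars < 1 or self.n_formats < 1:
            raise ValueError("design must have at least one exemplar and format")

    @property
    def n_distinct_videos(self) -> int:
        """Distinct main-experiment videos (exemplar x format x actor x object)."""
        return self.n_exemplars * self.n_formats * self.n_actors * self.n_objects

    @property
    def n_trials(self) -> int:
        """Main-session trial count (each distinct video repeated)."""
        return self.n_distinct_videos * self.n_repetitions

    @property
    def trials_per_cell(self) -> int:
        """Trials per exemplar x format cell."""
        return self.n_actors * self.n_objects * self.n_repetitions

    @property
    def n_control_trials(self) -> int:
        return self.n_control_videos * self.n_control_trials_per_video


def substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-keyed child RNG stream.

    A single session seed expands into independent Philox streams keyed by
    integer path components (e.g. unit index, repeat index), so any part of
    a dataset can be regenerated without replaying the whole session.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.Philox(ss))
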