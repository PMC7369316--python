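"""Ground-truth-labelled synthetic spike-train generator.

Emulates a session of the factorial observed-manipulative-action (OMA)
design: 7 exemplars x 4 visual formats x 2 actors x 2 objects x 3
repetitions = 336 trials, a 500-ms pre-onset baseline and a 2.6-s video,
plus a 9-video natural-scene control session with per-video motion and
contrast covariates.

Each unit belongs to a generative class that fixes how its expected
firing rate combines format and exemplar information during the video:

``multiplicative_stable``
    rate = baseline + gain_j * tuning_i — the exemplar preference order is
    the same in every format, only rescaled (gain field).
``additive``
    rate = baseline + gain_j + tuning_i.
``mixed_unstable``
    an independent exemplar-tuning row per format; no cross-format rank
    relation.
``format_only``
    rate depends on the format alone.
``untuned``
    constant baseline.
``motion_coupled``
    (control sessions) rate = baseline + slope * motion covariate.

The time course separates a *static* format component (a step at video
onset) from a *dynamic* action component that ramps linearly from
onset + 300 ms to the end of epoch 2 (1.5 s) and then holds.  The ramp
peaks at twice the nominal amplitude so that the epoch-2 *mean* of the
dynamic component equals the nominal amplitude: the class equations above
hold exactly as epoch-2 expectations.

Spikes are drawn from an inhomogeneous Poisson process by thinning with
1-ms rate resolution, one independent RNG substream per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    ACTORS,
    DesignSpec,
    EXEMPLARS,
    FORMAT_FACTORS,
    FORMATS,
    N_EXEMPLARS,
    N_FORMATS,
    OBJECTS,
    substream,
)
from .recording import RecordingSet

UNIT_CLASSES = (
    "multiplicative_stable",
    "additive",
    "mixed_unstable",
    "format_only",
    "untuned",
    "motion_coupled",
)

RAMP_START_S = 0.3
RAMP_END_S = 1.5
RATE_RESOLUTION_S = 1e-3


@dataclass
class UnitSpec:
    """Generative parameters of one synthetic unit.

    ``exemplar_tuning`` holds seven nonnegative weights (one per OMA),
    ``format_gain`` four positive gains (one per format), and
    ``per_format_tuning`` a 4 x 7 array used only by mixed-selectivity
    units.  ``motion_slope`` couples control-session rates to the motion
    covariate; ``video_tuning`` optionally gives explicit per-video
    amplitudes for the nine control videos.
    """

    unit_id: str
    unit_class: str
    baseline_rate: float = 10.0
    exemplar_tuning: np.ndarray = field(default_factory=lambda: np.zeros(N_EXEMPLARS))
    format_gain: np.ndarray = field(default_factory=lambda: np.ones(N_FORMATS))
    per_format_tuning: np.ndarray | None = None
    motion_slope: float = 0.0
    video_tuning: np.ndarray | None = None
    isolation: str = "single"

    def __post_init__(self) -> None:
        self.exemplar_tuning = np.asarray(self.exemplar_tuning, dtype=float)
        self.format_gain = np.asarray(self.format_gain, dtype=float)
        if self.per_format_tuning is not None:
            self.per_format_tuning = np.asarray(self.per_format_tuning, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit class {self.unit_class!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be nonnegative")
        if self.exemplar_tuning.shape != (N_EXEMPLARS,) or (self.exemplar_tuning < 0).any():
            raise ValueError("exemplar_tuning must be 7 nonnegative weights")
        if self.format_gain.shape != (N_FORMATS,):
            raise ValueError("format_gain must have 4 entries")
        if self.unit_class in ("multiplicative_stable", "format_only") and (
            self.format_gain <= 0
        ).any():
            raise ValueError("format gains must be positive")
        if self.unit_class == "mixed_unstable":
            if self.per_format_tuning is None or self.per_format_tuning.shape != (
                N_FORMATS,
                N_EXEMPLARS,
            ):
                raise ValueError("mixed_unstable units need a 4x7 per_format_tuning")
            if (self.per_format_tuning < 0).any():
                raise ValueError("per_format_tuning must be nonnegative")
        if self.expected_epoch2_rates().min() < 0:
            raise ValueError("negative expected rate")

    # ------------------------------------------------------------ rate model
    def _components(self) -> tuple[np.ndarray, np.ndarray]:
        """(static 4x7, dynamic 4x7) rate components above baseline."""
        static = np.zeros((N_FORMATS, N_EXEMPLARS))
        dynamic = np.zeros((N_FORMATS, N_EXEMPLARS))
        if self.unit_class == "multiplicative_stable":
            dynamic = np.outer(self.format_gain, self.exemplar_tuning)
        elif self.unit_class == "additive":
            static = np.repeat(self.format_gain[:, None], N_EXEMPLARS, axis=1)
            dynamic = np.repeat(self.exemplar_tuning[None, :], N_FORMATS, axis=0)
        elif self.unit_class == "mixed_unstable":
            dynamic = self.per_format_tuning.copy()
        elif self.unit_class == "format_only":
            static = np.repeat(self.format_gain[:, None], N_EXEMPLARS, axis=1)
        return static, dynamic

    def expected_epoch2_rates(self) -> np.ndarray:
        """Expected 4 (format) x 7 (exemplar) mean rate in epoch 2."""
        static, dynamic = self._components()
        return self.baseline_rate + static + dynamic

    def tuning_amplitude(self) -> float:
        """Peak-to-peak spread of the expected epoch-2 condition rates."""
        r = self.expected_epoch2_rates()
        return float(r.max() - r.min())

    def rate_on_grid(self, t_grid: np.ndarray, video_duration_s: float) -> np.ndarray:
        """Expected rate (4 x 7 x len(t_grid)) at each time point."""
        static, dynamic = self._components()
        in_video = (t_grid >= 0) & (t_grid < video_duration_s)
        ramp = np.clip((t_grid - RAMP_START_S) / (RAMP_END_S - RAMP_START_S), 0.0, 1.0)
        d_env = 2.0 * ramp * in_video
        lam = (
            self.baseline_rate
            + static[:, :, None] * in_video[None, None, :]
            + dynamic[:, :, None] * d_env[None, None, :]
        )
        return lam


def _simulate_unit(
    rng: np.random.Generator,
    lam_grid: np.ndarray,
    cond_of_trial: np.ndarray,
    t_lo: float,
    t_hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinning simulation for all trials of one unit.

    ``lam_grid`` is (n_conditions, n_grid) expected rate sampled every
    millisecond on [t_lo, t_hi); ``cond_of_trial`` maps each trial to its
    condition row.  Returns (trial_index, time_s) of accepted spikes,
    sorted by trial then time.
    """
    if (lam_grid < 0).any():
        raise ValueError("negative expected rate")
    total_t = t_hi - t_lo
    lam_max = lam_grid.max(axis=1)[cond_of_trial]
    n_cand = rng.poisson(np.maximum(lam_max, 0.0) * total_t)
    n_total = int(n_cand.sum())
    if n_total == 0:
        return np.empty(0, dtype=int), np.empty(0)
    trial = np.repeat(np.arange(len(cond_of_trial)), n_cand)
    t = rng.uniform(t_lo, t_hi, n_total)
    gi = np.minimum(((t - t_lo) / RATE_RESOLUTION_S).astype(int), lam_grid.shape[1] - 1)
    lam_t = lam_grid[cond_of_trial[trial], gi]
    keep = rng.random(n_total) * lam_max[trial] < lam_t
    trial, t = trial[keep], t[keep]
    order = np.lexsort((t, trial))
    return trial[order], t[order]


def _main_trial_table(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for rep in range(1, design.n_repetitions + 1):
        for fmt in FORMATS:
            posture, viewpoint = FORMAT_FACTORS[fmt]
            for ex in EXEMPLARS:
                for actor in ACTORS:
                    for obj in OBJECTS:
                        rows.append((ex, fmt, posture, viewpoint, actor, obj, rep))
    df = pd.DataFrame(
        rows,
        columns=["exemplar", "format", "posture", "viewpoint", "actor", "object", "repetition"],
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df


def _ground_truth(population: list[UnitSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in population],
            "unit_class": [u.unit_class for u in population],
            "baseline_rate": [u.baseline_rate for u in population],
            "tuning_amplitude": [u.tuning_amplitude() for u in population],
            "motion_slope": [u.motion_slope for u in population],
        }
    )


def generate_main_dataset(
    population: list[UnitSpec],
    design: DesignSpec | None = None,
    seed: int = 0,
    actor_object_jitter: float = 0.05,
) -> RecordingSet:
    """Simulate one main-experiment session.

    Every unit gets an independent RNG substream derived from `seed`, so
    the same seed always yields a byte-identical spike table.  Actor and
    object identity add a small static zero-mean rate offset during the
    video (`actor_object_jitter` as a fraction of the unit's tuning
    amplitude), emulating the residual visual variability of the four
    variants of each exemplar x format video.
    """
    design = design or DesignSpec()
    trials = _main_trial_table(design, substream(seed, 0))
    t_lo, t_hi = -design.baseline_window_s, design.video_duration_s
    n_grid = int(round((t_hi - t_lo) / RATE_RESOLUTION_S))
    t_grid = t_lo + RATE_RESOLUTION_S * (np.arange(n_grid) + 0.5)
    in_video = (t_grid >= 0) & (t_grid < design.video_duration_s)

    fmt_idx = trials["format"].map({f: i for i, f in enumerate(FORMATS)}).to_numpy()
    ex_idx = trials["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy()
    ac_idx = trials["actor"].map({a: i for i, a in enumerate(ACTORS)}).to_numpy()
    ob_idx = trials["object"].map({o: i for i, o in enumerate(OBJECTS)}).to_numpy()
    # condition index over format x exemplar x actor x object
    cond = ((fmt_idx * N_EXEMPLARS + ex_idx) * 2 + ac_idx) * 2 + ob_idx

    spike_frames = []
    for ui, unit in enumerate(population):
        rng = substream(seed, 1, ui)
        jit_scale = actor_object_jitter * unit.tuning_amplitude()
        actor_off = rng.normal(0.0, jit_scale, 2) if jit_scale > 0 else np.zeros(2)
        object_off = rng.normal(0.0, jit_scale, 2) if jit_scale > 0 else np.zeros(2)
        lam = unit.rate_on_grid(t_grid, design.video_duration_s)  # 4x7xg
        lam = lam[:, :, None, None, :] + (
            (actor_off[:, None] + object_off[None, :])[None, None, :, :, None]
            * in_video[None, None, None, None, :]
        )
        lam_grid = np.clip(lam, 0.0, None).reshape(-1, n_grid)
        tr, t = _simulate_unit(rng, lam_grid, cond, t_lo, t_hi)
        spike_frames.append(
            pd.DataFrame(
                {
                    "unit_id": unit.unit_id,
                    "trial_id": trials["trial_id"].to_numpy()[tr],
                    "time_s": t,
                }
            )
        )
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "trial_id", "time_s"])
    )
    units = pd.DataFrame(
        {"unit_id": [u.unit_id for u in population], "isolation": [u.isolation for u in population]}
    )
    return RecordingSet(
        units=units,
        trials=trials,
        spikes=spikes,
        baseline_window_s=design.baseline_window_s,
        video_duration_s=design.video_duration_s,
        kind="main",
        ground_truth=_ground_truth(population),
    )


def default_control_covariates(design: DesignSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-video motion and contrast scalars on [0, 1], well spread."""
    design = design or DesignSpec()
    rng = substream(seed, 9)
    n = design.n_control_videos
    motion = rng.permutation(np.linspace(0.05, 0.95, n))
    contrast = rng.permutation(np.linspace(0.1, 0.9, n))
    return pd.DataFrame({"video": np.arange(n), "motion": motion, "contrast": contrast})


def generate_control_dataset(
    population: list[UnitSpec],
    design: DesignSpec | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> tuple[RecordingSet, pd.DataFrame]:
    """Simulate one natural-video control session.

    ``motion_coupled`` units fire at baseline + slope x motion covariate
    during the video; video-tuned classes use ``video_tuning`` (or their
    exemplar tuning cycled over the nine videos); untuned units stay at
    baseline.  Returns the session and the covariate table used.
    """
    design = design or DesignSpec()
    if covariates is None:
        covariates = default_control_covariates(design, seed)
    covariates = covariates.sort_values("video").reset_index(drop=True)
    if len(covariates) != design.n_control_videos:
        raise ValueError("one covariate row per control video required")
    n_vid = design.n_control_videos
    rng0 = substream(seed, 2)
    video = np.repeat(np.arange(n_vid), design.n_control_trials_per_video)
    rep = np.tile(np.arange(1, design.n_control_trials_per_video + 1), n_vid)
    order = rng0.permutation(len(video))
    trials = pd.DataFrame(
        {"trial_id": np.arange(len(video)), "video": video[order], "repetition": rep[order]}
    )
    t_lo, t_hi = -design.baseline_window_s, design.control_video_duration_s
    n_grid = int(round((t_hi - t_lo) / RATE_RESOLUTION_S))
    t_grid = t_lo + RATE_RESOLUTION_S * (np.arange(n_grid) + 0.5)
    in_video = (t_grid >= 0) & (t_grid < design.control_video_duration_s)
    motion = covariates["motion"].to_numpy()

    spike_frames = []
    for ui, unit in enumerate(population):
        rng = substream(seed, 3, ui)
        if unit.unit_class == "motion_coupled":
            amp = unit.motion_slope * motion
        elif unit.unit_class == "untuned":
            amp = np.zeros(n_vid)
        elif unit.video_tuning is not None:
            amp = np.asarray(unit.video_tuning, dtype=float)
        else:
            amp = np.resize(unit.exemplar_tuning, n_vid)
        lam_grid = np.clip(
            unit.baseline_rate + amp[:, None] * in_video[None, :], 0.0, None
        )
        tr, t = _simulate_unit(rng, lam_grid, trials["video"].to_numpy(), t_lo, t_hi)
        spike_frames.append(
            pd.DataFrame({"unit_id": unit.unit_id, "trial_id": tr, "time_s": t})
        )
    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "trial_id", "time_s"])
    )
    units = pd.DataFrame(
        {"unit_id": [u.unit_id for u in population], "isolation": [u.isolation for u in population]}
    )
    rec = RecordingSet(
        units=units,
        trials=trials,
        spikes=spikes,
        baseline_window_s=design.baseline_window_s,
        video_duration_s=design.control_video_duration_s,
        kind="control",
        ground_truth=_ground_truth(population),
    )
    return rec, covariates


# --------------------------------------------------------------- populations
#: Graded exemplar-preference profile: a clear best action with an
#: exponential fall-off over the remaining ranks.
EXEMPLAR_PROFILE = np.exp(-np.arange(N_EXEMPLARS) / 1.0)
#: Sparse additive format-preference profile for additive / format-only units.
FORMAT_PROFILE = np.exp(-np.arange(N_FORMATS) / 0.7)


def make_unit(
    unit_class: str,
    unit_id: str,
    rng: np.random.Generator,
    baseline_range: tuple[float, float] = (1.0, 5.0),
    tuning_peak: float = 25.0,
    gain_range: tuple[float, float] = (0.6, 1.6),
    motion_slope: float = 20.0,
) -> UnitSpec:
    """Draw one unit of the given class with field-typical parameters.

    Spontaneous rates span 1-5 spikes/s (visual parietal units fire
    little at rest) and video responses reach several-fold above them:
    exemplar tuning is a randomly permuted graded-preference profile
    peaking at `tuning_peak` spikes/s.  Multiplicative units rescale that
    profile by per-format gains drawn from `gain_range`; additive and
    format-only units shift rate by a sparse per-format offset (peak
    0.8 x `tuning_peak`).
    """
    baseline = rng.uniform(*baseline_range)
    tuning = tuning_peak * rng.permutation(EXEMPLAR_PROFILE)
    offset_gains = 0.8 * tuning_peak * rng.permutation(FORMAT_PROFILE)
    kw: dict = {"baseline_rate": baseline}
    if unit_class == "multiplicative_stable":
        kw.update(exemplar_tuning=tuning, format_gain=rng.uniform(*gain_range, N_FORMATS))
    elif unit_class == "additive":
        kw.update(exemplar_tuning=tuning, format_gain=offset_gains)
    elif unit_class == "mixed_unstable":
        pft = tuning_peak * np.stack(
            [rng.permutation(EXEMPLAR_PROFILE) for _ in range(N_FORMATS)]
        )
        kw.update(per_format_tuning=pft)
    elif unit_class == "format_only":
        kw.update(format_gain=np.maximum(offset_gains, 1e-6))
    elif unit_class == "motion_coupled":
        kw.update(motion_slope=motion_slope)
    elif unit_class != "untuned":
        raise ValueError(f"unknown unit class {unit_class!r}")
    return UnitSpec(unit_id=unit_id, unit_class=unit_class, **kw)


def make_population(
    class_counts: dict[str, int],
    seed: int = 0,
    **unit_kwargs,
) -> list[UnitSpec]:
    """Build a labelled population with the given number of units per class."""
    rng = substream(seed, 7)
    population = []
    i = 0
    for cls, n in class_counts.items():
        for _ in range(n):
            population.append(make_unit(cls, f"u{i:04d}", rng, **unit_kwargs))
            i += 1
    return population
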