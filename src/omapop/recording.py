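"""Trial-aligned spike data model, file I/O, epoching and binning.

Spike times are stored in seconds, double precision, with video onset at
t = 0.  Bins are half-open, ``[start, start + width)``, and every binned
quantity is reported at the *start* of its interval.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MAIN_TRIAL_COLUMNS = (
    "trial_id", "exemplar", "format", "posture", "viewpoint",
    "actor", "object", "repetition",
)
CONTROL_TRIAL_COLUMNS = ("trial_id", "video", "repetition")


@dataclass
class RecordingSet:
    """One session of trial-aligned spiking data.

    Parameters
    ----------
    units
        One row per unit: ``unit_id`` and ``isolation`` ("single"/"multi").
    trials
        One row per trial with all condition labels.
    spikes
        Long table ``(unit_id, trial_id, time_s)``; times relative to onset.
    baseline_window_s
        Pre-onset recording extent (positive number of seconds).
    video_duration_s
        Video length in seconds.
    kind
        "main" (factorial OMA design) or "control" (natural videos).
    ground_truth
        Optional generator sidecar with per-unit generative labels.
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    baseline_window_s: float = 0.5
    video_duration_s: float = 2.6
    kind: str = "main"
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.units["unit_id"].duplicated().any():
            raise ValueError("duplicate unit ids")
        if self.trials["trial_id"].duplicated().any():
            raise ValueError("duplicate trial ids")
        required = MAIN_TRIAL_COLUMNS if self.kind == "main" else CONTROL_TRIAL_COLUMNS
        missing = set(required) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        if len(self.spikes):
            t = self.spikes["time_s"].to_numpy()
            if t.min() < -self.baseline_window_s - 1e-9 or t.max() > self.video_duration_s + 1e-9:
                raise ValueError("spike timestamps outside the trial extent")
            if not set(self.spikes["trial_id"]).issubset(set(self.trials["trial_id"])):
                raise ValueError("spikes reference unknown trials")

    @property
    def unit_ids(self) -> np.ndarray:
        return self.units["unit_id"].to_numpy()

    @property
    def trial_ids(self) -> np.ndarray:
        return self.trials["trial_id"].to_numpy()

    # ------------------------------------------------------------------ IO
    def to_dir(self, path: str | Path) -> None:
        """Write the session as columnar text tables plus a JSON header."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.units.to_csv(path / "units.csv", index=False)
        self.trials.to_csv(path / "trials.csv", index=False)
        self.spikes.to_csv(path / "spikes.csv", index=False)
        meta = {
            "baseline_window_s": self.baseline_window_s,
            "video_duration_s": self.video_duration_s,
            "kind": self.kind,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        if self.ground_truth is not None:
            self.ground_truth.to_csv(path / "ground_truth.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "RecordingSet":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        gt_path = path / "ground_truth.csv"
        return cls(
            units=pd.read_csv(path / "units.csv"),
            trials=pd.read_csv(path / "trials.csv"),
            spikes=pd.read_csv(path / "spikes.csv"),
            ground_truth=pd.read_csv(gt_path) if gt_path.exists() else None,
            **meta,
        )


@dataclass
class BinnedTensor:
    """Unit x trial x time-bin firing rates (spikes/s)."""

    rates: np.ndarray
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    bin_starts: np.ndarray
    bin_width_s: float
    bin_step_s: float

    def __post_init__(self) -> None:
        if (self.rates < 0).any():
            raise ValueError("negative firing rates")

    @property
    def counts(self) -> np.ndarray:
        """Integer spike counts per bin (rate x width, rounded)."""
        return np.rint(self.rates * self.bin_width_s).astype(np.int64)

    def unit_index(self, unit_ids) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.unit_ids)}
        return np.array([lookup[u] for u in np.atleast_1d(unit_ids)])


def _count_in_windows(
    recordings: RecordingSet,
    windows: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike counts per (unit, trial, window); windows are half-open."""
    unit_ids = recordings.unit_ids
    trial_ids = recordings.trial_ids
    u_lookup = {u: i for i, u in enumerate(unit_ids)}
    t_lookup = {t: i for i, t in enumerate(trial_ids)}
    n_pairs = len(unit_ids) * len(trial_ids)
    counts = np.zeros((len(unit_ids), len(trial_ids), len(windows)), dtype=np.int64)
    if len(recordings.spikes):
        su = recordings.spikes["unit_id"].map(u_lookup).to_numpy()
        st = recordings.spikes["trial_id"].map(t_lookup).to_numpy()
        times = recordings.spikes["time_s"].to_numpy()
        pair = su * len(trial_ids) + st
        for k, (lo, hi) in enumerate(windows):
            m = (times >= lo) & (times < hi)
            c = np.bincount(pair[m], minlength=n_pairs)
            counts[:, :, k] = c.reshape(len(unit_ids), len(trial_ids))
    return counts, unit_ids, trial_ids


def bin_starts_for(window: tuple[float, float], width_s: float, step_s: float) -> np.ndarray:
    """Starts of all complete bins of `width_s` advancing by `step_s`."""
    lo, hi = window
    n = int(np.floor((hi - lo - width_s) / step_s + 1e-9)) + 1
    if n < 1:
        raise ValueError("window shorter than one bin")
    return lo + step_s * np.arange(n)


def bin_rates(
    recordings: RecordingSet,
    width_s: float,
    step_s: float,
    window: tuple[float, float],
) -> BinnedTensor:
    """Convert raster spikes into (possibly overlapping) binned rates.

    Rate in a bin is spike count / width; bins advance by `step_s` and a
    partial bin that would overhang the window is excluded.
    """
    if width_s <= 0 or step_s <= 0:
        raise ValueError("bin width and step must be positive")
    if window[1] <= window[0]:
        raise ValueError("empty binning window")
    if step_s > width_s:
        log.warning("bin step %.3f s exceeds width %.3f s: gaps between bins", step_s, width_s)
    starts = bin_starts_for(window, width_s, step_s)
    counts, unit_ids, trial_ids = _count_in_windows(
        recordings, [(s, s + width_s) for s in starts]
    )
    return BinnedTensor(
        rates=counts / width_s,
        unit_ids=unit_ids,
        trial_ids=trial_ids,
        bin_starts=starts,
        bin_width_s=width_s,
        bin_step_s=step_s,
    )


def epoch_rates(
    recordings: RecordingSet,
    epochs: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Per-trial mean firing rate in each named epoch.

    Returns a tidy frame ``(unit_id, trial_id, epoch, rate)``.
    """
    names = list(epochs)
    windows = [epochs[n] for n in names]
    for lo, hi in windows:
        if hi <= lo:
            raise ValueError("empty epoch window")
    counts, unit_ids, trial_ids = _count_in_windows(recordings, windows)
    widths = np.array([hi - lo for lo, hi in windows])
    rates = counts / widths
    nu, nt, ne = rates.shape
    return pd.DataFrame(
        {
            "unit_id": np.repeat(unit_ids, nt * ne),
            "trial_id": np.tile(np.repeat(trial_ids, ne), nu),
            "epoch": np.tile(names, nu * nt),
            "rate": rates.ravel(),
        }
    )


def net_population_activity(
    binned: BinnedTensor,
    unit_subset=None,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
) -> pd.DataFrame:
    """Baseline-subtracted population activity time course.

    For each unit the trial-averaged rate in every bin has the unit's mean
    baseline activity subtracted; the result is averaged across units.
    Returns ``(bin_start, mean, sem)``.
    """
    if unit_subset is None:
        idx = np.arange(len(binned.unit_ids))
    else:
        idx = binned.unit_index(unit_subset)
    if len(idx) == 0:
        raise ValueError("empty unit subset")
    per_unit = binned.rates[idx].mean(axis=1)  # unit x bin trial average
    in_base = (binned.bin_starts >= baseline_window[0] - 1e-9) & (
        binned.bin_starts + binned.bin_width_s <= baseline_window[1] + 1e-9
    )
    if not in_base.any():
        raise ValueError("no bins fall inside the baseline window")
    net = per_unit - per_unit[:, in_base].mean(axis=1, keepdims=True)
    sem = net.std(axis=0, ddof=1) / np.sqrt(len(idx)) if len(idx) > 1 else np.zeros(net.shape[1])
    return pd.DataFrame(
        {"bin_start": binned.bin_starts, "mean": net.mean(axis=0), "sem": sem}
    )
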