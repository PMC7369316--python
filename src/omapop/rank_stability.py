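"""Across-format rank stability of exemplar preference (RSI).

For every sliding bin the seven exemplars are ranked by trial-averaged
firing rate within each of the four formats.  With a reference format
fixed, the rank Rf_i of the reference format's preferred exemplar is
looked up in each of the n = 3 test formats and the raw index is

    RSIr = 1 + sum_i (1 - (1/7) * (Rf_i - 1)),

ranging from 10/7 (preferred exemplar ranked last everywhere) to 4
(preferred everywhere).  Normalizing by (max - min) maps the index onto
[0, 1]; over the 343 possible rank triples it takes exactly 19 evenly
spaced values with mean 1/2 under independent uniform ranks.  Being
rank-based, the index is insensitive to any monotone rescaling of a
unit's firing rates within a format.

Two shuffling nulls are provided: an *unconstrained* null that replaces
every test-format rank with an independent uniform draw on 1..7, and a
*constrained* null that remaps each rank value consistently across all
bins of a test format, preserving the temporal structure of selectivity
changes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import FORMATS, N_EXEMPLARS, substream

log = logging.getLogger(__name__)

RSI_MIN = 1.0 + 3.0 * (1.0 / 7.0)  # 10/7, preferred exemplar ranked 7 everywhere
RSI_MAX = 4.0
N_TEST_FORMATS = 3


def rank_exemplars(means: np.ndarray) -> np.ndarray:
    """Ranks 1..7 of exemplar means, 1 = highest; ties break by exemplar order."""
    means = np.asarray(means, dtype=float)
    if means.shape[-1] != N_EXEMPLARS or not np.isfinite(means).all():
        raise ValueError("need 7 finite exemplar means")
    # stable argsort of the negated means: ties resolve in exemplar order
    order = np.argsort(-means, axis=-1, kind="stable")
    ranks = np.empty(means.shape, dtype=int)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1, N_EXEMPLARS + 1), means.shape), axis=-1
    )
    return ranks


def rsi_raw(rf: np.ndarray) -> float:
    """Raw rank stability index from the 3 test-format ranks."""
    rf = np.asarray(rf)
    if rf.shape[-1] != N_TEST_FORMATS or ((rf < 1) | (rf > 7)).any():
        raise ValueError("Rf must be 3 ranks in 1..7")
    return 1.0 + (1.0 - (rf - 1) / 7.0).sum(axis=-1)


def rsi_normalize(rsir) -> float:
    """Map raw RSI from [10/7, 4] onto [0, 1]."""
    rsir = np.asarray(rsir, dtype=float)
    if ((rsir < RSI_MIN - 1e-9) | (rsir > RSI_MAX + 1e-9)).any():
        raise ValueError("raw RSI outside [10/7, 4]")
    return (rsir - RSI_MIN) / (RSI_MAX - RSI_MIN)


@dataclass
class RSITimecourse:
    """Per-bin rank stability of one unit."""

    bin_starts: np.ndarray
    ranks: np.ndarray        # (4 formats, n_bins, 7) exemplar ranks
    rf: np.ndarray           # (n_bins, 3) test-format ranks of the reference best
    rsi_raw: np.ndarray      # (n_bins,)
    rsi: np.ndarray          # (n_bins,) normalized
    total_score: float
    reference_format: str
    bin_width_s: float


def rsi_from_ranks(
    ranks: np.ndarray, reference: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rf, rsi_raw, rsi) per bin from (4, n_bins, 7) rank arrays."""
    test = [j for j in range(ranks.shape[0]) if j != reference]
    best = ranks[reference].argmin(axis=-1)  # exemplar with rank 1 per bin
    rf = np.stack(
        [ranks[j][np.arange(ranks.shape[1]), best] for j in test], axis=-1
    )
    raw = rsi_raw(rf)
    return rf, raw, rsi_normalize(raw)


def format_exemplar_timecourses(binned, trials) -> np.ndarray:
    """Trial-averaged rates (n_units, 4 formats, 7 exemplars, n_bins).

    ``binned`` is a BinnedTensor over the task period and ``trials`` the
    session trial table with ``format`` and ``exemplar`` columns.
    """
    from .design import EXEMPLARS

    n_units, _, n_bins = binned.rates.shape
    out = np.zeros((n_units, len(FORMATS), N_EXEMPLARS, n_bins))
    for j, f in enumerate(FORMATS):
        for i, e in enumerate(EXEMPLARS):
            m = ((trials["format"] == f) & (trials["exemplar"] == e)).to_numpy()
            if not m.any():
                raise ValueError(f"no trials for {e}/{f}")
            out[:, j, i, :] = binned.rates[:, m, :].mean(axis=1)
    return out


def rsi_timecourse(
    format_exemplar_rates: np.ndarray,
    bin_starts: np.ndarray,
    bin_width_s: float = 0.5,
    reference_format: str = "stand_lateral",
    score_window: tuple[float, float] = (0.0, 1.5),
) -> RSITimecourse:
    """Time-resolved RSI of one unit.

    ``format_exemplar_rates`` is (4 formats, 7 exemplars, n_bins)
    trial-averaged rates (canonical format order).  The total score sums
    the normalized RSI over bins whose windows lie entirely within
    `score_window` (epochs 1 + 2 by default).
    """
    rates = np.asarray(format_exemplar_rates, dtype=float)
    if rates.shape[0] != len(FORMATS):
        raise ValueError("rates for all four formats required")
    ref = FORMATS.index(reference_format)
    ranks = np.stack(
        [rank_exemplars(rates[j].T) for j in range(len(FORMATS))]
    )  # (4, n_bins, 7)
    rf, raw, rsi = rsi_from_ranks(ranks, ref)
    in_score = (bin_starts >= score_window[0] - 1e-9) & (
        bin_starts + bin_width_s <= score_window[1] + 1e-9
    )
    return RSITimecourse(
        bin_starts=np.asarray(bin_starts),
        ranks=ranks,
        rf=rf,
        rsi_raw=raw,
        rsi=rsi,
        total_score=float(rsi[in_score].sum()),
        reference_format=reference_format,
        bin_width_s=bin_width_s,
    )


def shuffle_null(
    timecourse: RSITimecourse,
    n_perms: int = 1000,
    seed: int = 0,
    constrained: bool = False,
    bijective: bool = False,
) -> np.ndarray:
    """Null normalized-RSI samples, (n_perms, n_bins).

    Unconstrained: every test-format rank is replaced by an independent
    uniform integer 1..7 in every bin.  Constrained: per test format one
    random value map {1..7} -> {1..7} is applied to all bins, keeping
    the temporal structure of rank changes (`bijective` draws the map as
    a permutation instead of independent draws with collisions).
    """
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    rng = substream(seed, 31)
    n_bins = timecourse.rf.shape[0]
    out = np.empty((n_perms, n_bins))
    for k in range(n_perms):
        if constrained:
            rf = np.empty_like(timecourse.rf)
            for j in range(N_TEST_FORMATS):
                if bijective:
                    mapping = rng.permutation(7) + 1
                else:
                    mapping = rng.integers(1, 8, size=7)
                rf[:, j] = mapping[timecourse.rf[:, j] - 1]
        else:
            rf = rng.integers(1, 8, size=timecourse.rf.shape)
        out[k] = rsi_normalize(rsi_raw(rf))
    return out


def enumerate_rsi_values() -> pd.DataFrame:
    """Exact normalized-RSI distribution under independent uniform ranks.

    Enumerates all 7^3 = 343 equally likely test-format rank triples and
    returns each distinct normalized value with its probability.
    """
    values: dict[float, int] = {}
    for rf in itertools.product(range(1, 8), repeat=N_TEST_FORMATS):
        v = round(float(rsi_normalize(rsi_raw(np.array(rf)))), 12)
        values[v] = values.get(v, 0) + 1
    df = pd.DataFrame(
        sorted(values.items()), columns=["rsi", "count"]
    )
    df["probability"] = df["count"] / df["count"].sum()
    return df


def stability_split(total_scores: pd.Series) -> pd.DataFrame:
    """Median split of units into relatively stable vs unstable.

    Units are sorted by total RSI score descending; the top floor(n/2)
    are labelled stable and the rest unstable.
    """
    if len(total_scores) < 2:
        raise ValueError("need at least two units to split")
    order = total_scores.sort_values(ascending=False, kind="stable")
    n_stable = len(order) // 2
    labels = ["stable"] * n_stable + ["unstable"] * (len(order) - n_stable)
    return pd.DataFrame(
        {"unit_id": order.index, "total_score": order.to_numpy(), "stability_label": labels}
    )


def real_vs_null_ttest(real_scores: np.ndarray, null_scores: np.ndarray) -> dict[str, float]:
    """Two-sample t-test of real against null per-unit RSI scores."""
    t, p = stats.ttest_ind(real_scores, null_scores)
    return {"t": float(t), "p": float(p)}


def reference_robustness(
    per_unit_rates: list[np.ndarray],
    bin_starts: np.ndarray,
    bin_width_s: float = 0.5,
) -> pd.DataFrame:
    """Population mean RSI recomputed with each format as reference.

    ``per_unit_rates`` holds one (4, 7, n_bins) array per unit.  Errors
    out if fewer than four formats are present.
    """
    rows = []
    for ref in FORMATS:
        tcs = [
            rsi_timecourse(r, bin_starts, bin_width_s, reference_format=ref)
            for r in per_unit_rates
        ]
        mean_rsi = float(np.mean([tc.rsi.mean() for tc in tcs]))
        mean_score = float(np.mean([tc.total_score for tc in tcs]))
        rows.append((ref, mean_rsi, mean_score))
    return pd.DataFrame(rows, columns=["reference_format", "mean_rsi", "mean_total_score"])
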