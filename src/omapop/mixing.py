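"""Additive vs. multiplicative mixing of format and action identity.

For each unit a 4 (format) x 7 (exemplar) response matrix is split into
two trial halves.  From the training half O' the additive model predicts
A_ij = k1*E_i + k2*F_j (E: exemplar activations = column means, F: format
activations = row means, k1/k2 by least squares with no intercept) and
the multiplicative model predicts M = s1 * u1 v1', the best rank-1
approximation of O' by SVD (Eckart-Young).  Each prediction — and O'
itself, the split-half reliability ceiling — is scored by the squared
Pearson correlation with the held-out half O across the 28 cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import EXEMPLARS, FORMATS, N_EXEMPLARS, N_FORMATS, substream
from .recording import BinnedTensor

log = logging.getLogger(__name__)


@dataclass
class MixingFit:
    """Cross-validated additive and multiplicative fits of one unit."""

    E: np.ndarray
    F: np.ndarray
    k1: float
    k2: float
    A: np.ndarray
    u1: np.ndarray
    s1: float
    v1: np.ndarray
    M: np.ndarray
    r2_additive: float
    r2_multiplicative: float
    r2_observed: float


def cell_means(
    rates: np.ndarray, fmt_idx: np.ndarray, ex_idx: np.ndarray
) -> np.ndarray:
    """4 x 7 mean of per-trial `rates` grouped by format and exemplar."""
    out = np.zeros((N_FORMATS, N_EXEMPLARS))
    counts = np.zeros((N_FORMATS, N_EXEMPLARS))
    np.add.at(out, (fmt_idx, ex_idx), rates)
    np.add.at(counts, (fmt_idx, ex_idx), 1.0)
    if (counts == 0).any():
        raise ValueError("empty exemplar x format cell")
    return out / counts


def split_half_matrices(
    trial_rates: pd.DataFrame,
    mode: str = "even_odd",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split one unit's trials into two half matrices (O, O').

    ``trial_rates`` needs columns ``format``, ``exemplar``, ``trial_id``
    and ``rate``.  In ``even_odd`` mode the trials of each cell are taken
    in presentation order: even-numbered presentations build O and
    odd-numbered ones the training half O'.  In ``random`` mode each
    cell is split as evenly as possible at random with `seed`.
    """
    df = trial_rates.sort_values("trial_id")
    fmt_idx = df["format"].map({f: i for i, f in enumerate(FORMATS)}).to_numpy()
    ex_idx = df["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy()
    rates = df["rate"].to_numpy()
    cell = fmt_idx * N_EXEMPLARS + ex_idx
    in_a = np.zeros(len(df), dtype=bool)
    rng = substream(seed, 11) if seed is not None else None
    for c in range(N_FORMATS * N_EXEMPLARS):
        pos = np.flatnonzero(cell == c)
        if len(pos) < 2:
            raise ValueError("need at least two trials per cell to split")
        if mode == "even_odd":
            in_a[pos[::2]] = True
        elif mode == "random":
            if rng is None:
                raise ValueError("random mode requires a seed")
            perm = rng.permutation(len(pos))
            in_a[pos[perm[: (len(pos) + 1) // 2]]] = True
        else:
            raise ValueError(f"unknown split mode {mode!r}")
    O = cell_means(rates[in_a], fmt_idx[in_a], ex_idx[in_a])
    O_prime = cell_means(rates[~in_a], fmt_idx[~in_a], ex_idx[~in_a])
    return O, O_prime


def fit_additive(training: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, np.ndarray]:
    """Additive prediction from a training matrix.

    Returns (E, F, k1, k2, A) with E the 7 exemplar activations (column
    means), F the 4 format activations (row means) and A_ij = k1 E_i +
    k2 F_j, the two constants fit by ordinary least squares with no
    intercept over the 28 cells.
    """
    T = np.asarray(training, dtype=float)
    E = T.mean(axis=0)
    F = T.mean(axis=1)
    X = np.column_stack(
        [np.tile(E, N_FORMATS), np.repeat(F, N_EXEMPLARS)]
    )
    if np.linalg.matrix_rank(X) < 2:
        log.info("degenerate additive design (flat E and F); using k1 = k2 = 0.5")
        k1 = k2 = 0.5
    else:
        (k1, k2), *_ = np.linalg.lstsq(X, T.ravel(), rcond=None)
    A = k1 * E[None, :] + k2 * F[:, None]
    return E, F, float(k1), float(k2), A


def fit_multiplicative(training: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Leading rank-1 SVD reconstruction of the training matrix.

    Returns (u1, s1, v1, M) with M = s1 * u1 v1'; the u1*v1' product is
    sign-invariant, so M is unique whenever s1 > s2.
    """
    T = np.asarray(training, dtype=float)
    if not T.any():
        log.info("all-zero training matrix; multiplicative prediction is 0")
        return np.zeros(T.shape[0]), 0.0, np.zeros(T.shape[1]), np.zeros_like(T)
    u, s, vt = np.linalg.svd(T, full_matrices=False)
    if len(s) > 1 and np.isclose(s[0], s[1]):
        log.info("tied leading singular values; leading pair is not unique")
    M = s[0] * np.outer(u[:, 0], vt[0])
    return u[:, 0], float(s[0]), vt[0], M


def model_r2(prediction: np.ndarray, heldout: np.ndarray) -> float:
    """Squared Pearson correlation across the vectorized cells."""
    p = np.asarray(prediction, dtype=float).ravel()
    o = np.asarray(heldout, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("matrices must have matching shapes")
    if np.ptp(o) == 0:
        log.info("constant held-out matrix; r2 undefined")
        return np.nan
    if np.ptp(p) == 0:
        return 0.0
    r, _ = stats.pearsonr(p, o)
    return float(r**2)


def fit_unit(
    trial_rates: pd.DataFrame,
    mode: str = "even_odd",
    seed: int | None = None,
    fit_constants_on_heldout: bool = False,
) -> MixingFit:
    """Split, fit both models on O', and score all three against O.

    ``fit_constants_on_heldout`` re-estimates k1/k2 against the held-out
    matrix (an alternative reading of the regression step); the default
    keeps the fit entirely on the training half.
    """
    O, O_prime = split_half_matrices(trial_rates, mode=mode, seed=seed)
    E, F, k1, k2, A = fit_additive(O_prime)
    if fit_constants_on_heldout:
        X = np.column_stack([np.tile(E, N_FORMATS), np.repeat(F, N_EXEMPLARS)])
        if np.linalg.matrix_rank(X) == 2:
            (k1, k2), *_ = np.linalg.lstsq(X, O.ravel(), rcond=None)
            A = k1 * E[None, :] + k2 * F[:, None]
    u1, s1, v1, M = fit_multiplicative(O_prime)
    return MixingFit(
        E=E, F=F, k1=float(k1), k2=float(k2), A=A,
        u1=u1, s1=s1, v1=v1, M=M,
        r2_additive=model_r2(A, O),
        r2_multiplicative=model_r2(M, O),
        r2_observed=model_r2(O_prime, O),
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal Z.

    Falls back to the exact null distribution when either sample has
    fewer than eight observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if min(len(x), len(y)) < 8 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    _, tie_counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var_u = n1 * n2 / 12 * (n + 1 - tie_term)
    z = (res.statistic - n1 * n2 / 2) / np.sqrt(var_u) if var_u > 0 else 0.0
    return {"U": float(res.statistic), "Z": float(z), "p": float(res.pvalue)}


def compare_models_population(fits: pd.DataFrame) -> dict:
    """Medians and pairwise Mann-Whitney tests of the three r2 samples.

    ``fits`` needs columns ``r2_observed``, ``r2_multiplicative`` and
    ``r2_additive`` (one row per unit); NaN rows (constant held-out
    matrices) are dropped.
    """
    cols = ["r2_observed", "r2_multiplicative", "r2_additive"]
    clean = fits[cols].dropna()
    if len(clean) < 2:
        raise ValueError("population comparison needs at least two units")
    medians = clean.median().to_dict()
    tests = {}
    for a, b in (
        ("r2_observed", "r2_multiplicative"),
        ("r2_observed", "r2_additive"),
        ("r2_multiplicative", "r2_additive"),
    ):
        tests[f"{a}_vs_{b}"] = mann_whitney(clean[a].to_numpy(), clean[b].to_numpy())
    return {"medians": medians, "tests": tests, "n_units": len(clean)}


def fit_session(
    recordings,
    window: tuple[float, float] = (0.3, 1.5),
    mode: str = "even_odd",
    seed: int | None = None,
) -> pd.DataFrame:
    """Split-half model fits for every unit of a session at once.

    Returns one row per unit with the three cross-validated r2 values;
    equivalent to `fit_unit` on each unit but vectorized.
    """
    from .recording import _count_in_windows

    counts, unit_ids, _ = _count_in_windows(recordings, [window])
    rates = counts[:, :, 0] / (window[1] - window[0])  # units x trials
    trials = recordings.trials
    fmt_idx = trials["format"].map({f: i for i, f in enumerate(FORMATS)}).to_numpy()
    ex_idx = trials["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy()
    cell = fmt_idx * N_EXEMPLARS + ex_idx
    order = np.argsort(trials["trial_id"].to_numpy(), kind="stable")
    in_a = np.zeros(len(trials), dtype=bool)
    rng = substream(seed, 11) if seed is not None else None
    for c in range(N_FORMATS * N_EXEMPLARS):
        pos = order[cell[order] == c]
        if len(pos) < 2:
            raise ValueError("need at least two trials per cell to split")
        if mode == "even_odd":
            in_a[pos[::2]] = True
        elif mode == "random":
            if rng is None:
                raise ValueError("random mode requires a seed")
            perm = rng.permutation(len(pos))
            in_a[pos[perm[: (len(pos) + 1) // 2]]] = True
        else:
            raise ValueError(f"unknown split mode {mode!r}")

    def _half_means(mask):
        out = np.zeros((rates.shape[0], N_FORMATS * N_EXEMPLARS))
        for c in range(N_FORMATS * N_EXEMPLARS):
            m = mask & (cell == c)
            out[:, c] = rates[:, m].mean(axis=1)
        return out.reshape(-1, N_FORMATS, N_EXEMPLARS)

    OA, OB = _half_means(in_a), _half_means(~in_a)
    obs, mult, add = _batched_fits(OA, OB)
    return pd.DataFrame(
        {
            "unit_id": unit_ids,
            "r2_observed": obs,
            "r2_multiplicative": mult,
            "r2_additive": add,
        }
    )


# ----------------------------------------------------------- time-resolved
def _batched_fits(OA: np.ndarray, OB: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """r2 (observed, multiplicative, additive) for stacked 4x7 pairs.

    ``OA``/``OB`` have shape (batch, 4, 7): held-out and training halves.
    """
    B = OA.shape[0]
    # multiplicative: batched SVD of the training half
    u, s, vt = np.linalg.svd(OB)
    M = s[:, 0, None, None] * (u[:, :, 0, None] @ vt[:, None, 0, :])
    # additive: normal equations for [E, F] regressors
    E = OB.mean(axis=1)  # (B, 7)
    F = OB.mean(axis=2)  # (B, 4)
    Xe = np.tile(E, (1, N_FORMATS))
    Xf = np.repeat(F, N_EXEMPLARS, axis=1)
    t = OB.reshape(B, -1)
    g11 = (Xe * Xe).sum(1)
    g12 = (Xe * Xf).sum(1)
    g22 = (Xf * Xf).sum(1)
    b1 = (Xe * t).sum(1)
    b2 = (Xf * t).sum(1)
    det = g11 * g22 - g12**2
    safe = np.abs(det) > 1e-12 * np.maximum(g11 * g22, 1e-30)
    k1 = np.where(safe, (b1 * g22 - b2 * g12) / np.where(det == 0, 1, det), 0.5)
    k2 = np.where(safe, (b2 * g11 - b1 * g12) / np.where(det == 0, 1, det), 0.5)
    A = k1[:, None] * Xe + k2[:, None] * Xf

    def _r2(p: np.ndarray, o: np.ndarray) -> np.ndarray:
        p = p.reshape(len(p), -1)
        o = o.reshape(len(o), -1)
        pc = p - p.mean(1, keepdims=True)
        oc = o - o.mean(1, keepdims=True)
        num = (pc * oc).sum(1)
        den = np.sqrt((pc**2).sum(1) * (oc**2).sum(1))
        out = np.full(len(p), np.nan)
        ok = den > 0
        out[ok] = (num[ok] / den[ok]) ** 2
        return out

    return _r2(OB, OA), _r2(M, OA), _r2(A, OA)


def time_resolved_comparison(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    n_repeats: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
    min_run: int = 4,
) -> dict:
    """Sliding-window population comparison of the three r2 series.

    Per window and repeat, each unit's trials are split at random within
    every format x exemplar cell; both models are fit on one half and all
    three r2 values computed against the other.  Per-unit means over
    repeats feed sliding Wilcoxon signed-rank tests between the three
    series; significance is reported only for runs of at least `min_run`
    consecutive windows.
    """
    fmt_idx = trials["format"].map({f: i for i, f in enumerate(FORMATS)}).to_numpy()
    ex_idx = trials["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy()
    cell = fmt_idx * N_EXEMPLARS + ex_idx
    cells = [np.flatnonzero(cell == c) for c in range(N_FORMATS * N_EXEMPLARS)]
    if min(len(p) for p in cells) < 2:
        raise ValueError("need at least two trials per cell")
    n_units, _, n_bins = binned.rates.shape
    r2 = np.full((3, n_units, n_bins, n_repeats), np.nan)
    for rep in range(n_repeats):
        rng = substream(seed, 13, rep)
        in_a = np.zeros(binned.rates.shape[1], dtype=bool)
        for pos in cells:
            perm = rng.permutation(len(pos))
            in_a[pos[perm[: (len(pos) + 1) // 2]]] = True
        OA = np.stack(
            [binned.rates[:, in_a & (cell == c), :].mean(axis=1) for c in range(28)], axis=1
        )  # (units, 28, bins)
        OB = np.stack(
            [binned.rates[:, ~in_a & (cell == c), :].mean(axis=1) for c in range(28)], axis=1
        )
        OA = OA.transpose(0, 2, 1).reshape(-1, N_FORMATS, N_EXEMPLARS)
        OB = OB.transpose(0, 2, 1).reshape(-1, N_FORMATS, N_EXEMPLARS)
        obs, mult, add = _batched_fits(OA, OB)
        r2[0, :, :, rep] = obs.reshape(n_units, n_bins)
        r2[1, :, :, rep] = mult.reshape(n_units, n_bins)
        r2[2, :, :, rep] = add.reshape(n_units, n_bins)
    unit_means = np.nanmean(r2, axis=3)  # (3, units, bins)

    series = pd.DataFrame(
        {
            "bin_start": binned.bin_starts,
            "r2_observed": np.nanmean(unit_means[0], axis=0),
            "r2_multiplicative": np.nanmean(unit_means[1], axis=0),
            "r2_additive": np.nanmean(unit_means[2], axis=0),
        }
    )
    names = ("observed", "multiplicative", "additive")
    masks = {}
    for a in range(3):
        for b in range(a + 1, 3):
            p = np.ones(n_bins)
            for k in range(n_bins):
                xa, xb = unit_means[a, :, k], unit_means[b, :, k]
                ok = ~(np.isnan(xa) | np.isnan(xb))
                if ok.sum() >= 5 and np.ptp(xa[ok] - xb[ok]) > 0:
                    p[k] = stats.wilcoxon(xa[ok], xb[ok]).pvalue
            masks[f"{names[a]}_vs_{names[b]}"] = consecutive_runs_mask(p < alpha, min_run)
    return {"series": series, "masks": masks, "unit_means": unit_means}


def consecutive_runs_mask(sig: np.ndarray, min_run: int = 4) -> np.ndarray:
    """Keep only True entries belonging to runs of at least `min_run`."""
    sig = np.asarray(sig, dtype=bool)
    out = np.zeros_like(sig)
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j < len(sig) and sig[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out
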