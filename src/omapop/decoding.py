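"""Pseudopopulation decoding with a Poisson naive Bayes classifier.

Units recorded in different sessions are combined into pseudopopulation
"data points": for every condition each unit contributes one randomly
chosen trial per split, and a data point concatenates the units of one
split.  A Poisson naive Bayes (PNB) classifier is trained on spike
counts with leave-one-split-out cross-validation; training and testing
at every pair of time bins yields a temporal-generalization matrix.
Chance level is established by re-running the whole procedure with
class labels shuffled before pseudopopulation assembly; real accuracy
counts as significant only where it exceeds *all* shuffled values in
runs of at least four consecutive bins.

Counts are used raw (Poisson likelihoods need nonnegative integers).  A
z-scored correlation classifier is available as an alternative for
rate-normalized decoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import EXEMPLARS, FORMATS, substream
from .mixing import consecutive_runs_mask
from .recording import BinnedTensor

log = logging.getLogger(__name__)


@dataclass
class Pseudopopulation:
    """Split-structured pseudopopulation spike counts.

    ``counts`` has shape (n_splits, n_conditions, n_units, n_bins); the
    class label of data point (s, c) is ``labels[s, c]`` (an index into
    ``class_names``).
    """

    counts: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    bin_starts: np.ndarray

    @property
    def n_splits(self) -> int:
        return self.counts.shape[0]

    @property
    def n_data_points(self) -> int:
        return self.counts.shape[0] * self.counts.shape[1]


def pseudopopulation_counts(class_factor: str, trials_per_cell: int = 12) -> dict[str, int]:
    """Data-point bookkeeping for the three decoding configurations.

    With 12 trials per exemplar x format cell: format-independent OMA
    decoding pools 48 trials per exemplar into 48 splits of 7 points
    (336 data points); viewpoint or posture decoding uses 24 splits of 7
    (168 points); single-format OMA decoding 12 splits of 7 (84 points).
    """
    n_formats = len(FORMATS)
    n_ex = len(EXEMPLARS)
    if class_factor == "exemplar":
        n_splits = trials_per_cell * n_formats
    elif class_factor in ("viewpoint", "posture"):
        n_splits = trials_per_cell * n_formats // 2
    elif class_factor == "exemplar_one_format":
        n_splits = trials_per_cell
    else:
        raise ValueError(f"unknown decoding configuration {class_factor!r}")
    return {
        "n_splits": n_splits,
        "n_conditions": n_ex,
        "n_data_points": n_splits * n_ex,
    }


def build_pseudopopulation(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    class_factor: str = "exemplar",
    seed: int = 0,
    formats: list[str] | None = None,
) -> Pseudopopulation:
    """Assemble pseudopopulation data points for one decoding run.

    ``class_factor`` may be ``"exemplar"`` (OMA decoding; trials pooled
    over `formats`, default all) or ``"viewpoint"`` / ``"posture"``
    (format decoding: the seven exemplars remain the conditions and each
    split carries one level of the decoded factor, so a session yields
    24 x 7 = 168 data points).  Trials of every cell are assigned to
    splits at random without replacement.
    """
    rng = substream(seed, 17)
    if formats is not None:
        keep = trials["format"].isin(formats).to_numpy()
    else:
        keep = np.ones(len(trials), dtype=bool)
    sub = trials.loc[keep]
    t_pos = {t: i for i, t in enumerate(binned.trial_ids)}
    counts_all = binned.counts  # (units, trials, bins)
    n_units, _, n_bins = counts_all.shape

    ex_names = list(EXEMPLARS)
    if class_factor == "exemplar":
        groups = [(e, None) for e in ex_names]
        class_names = ex_names
    elif class_factor in ("viewpoint", "posture"):
        levels = sorted(sub[class_factor].unique())
        if len(levels) != 2:
            raise ValueError(f"{class_factor} must have two levels in the data")
        groups = [(e, lv) for e in ex_names for lv in levels]
        class_names = levels
    else:
        raise ValueError(f"unknown class factor {class_factor!r}")

    cell_trials = {}
    for e, lv in groups:
        m = sub["exemplar"] == e
        if lv is not None:
            m &= sub[class_factor] == lv
        ids = sub.loc[m, "trial_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError(f"no trials for exemplar {e!r}, level {lv!r}")
        cell_trials[(e, lv)] = np.array([t_pos[t] for t in ids])

    if class_factor == "exemplar":
        n_splits = min(len(v) for v in cell_trials.values())
        labels = np.tile(np.arange(len(ex_names)), (n_splits, 1))
        assign = {(e, None): np.arange(n_splits) for e in ex_names}
    else:
        # one data point per condition per split; the first half of the
        # splits carries level 0, the second half level 1
        splits_per_level = min(len(v) for v in cell_trials.values()) // 2
        n_splits = 2 * splits_per_level
        labels = np.zeros((n_splits, len(ex_names)), dtype=int)
        labels[splits_per_level:, :] = 1
        assign = {}
        for e in ex_names:
            assign[(e, class_names[0])] = np.arange(splits_per_level)
            assign[(e, class_names[1])] = splits_per_level + np.arange(splits_per_level)

    counts = np.zeros((n_splits, len(ex_names), n_units, n_bins), dtype=np.int64)
    for (e, lv), split_ids in assign.items():
        pool = cell_trials[(e, lv) if lv is not None else (e, None)]
        if len(pool) < len(split_ids):
            raise ValueError(
                f"exemplar {e!r}/{lv!r}: {len(pool)} trials cannot fill {len(split_ids)} splits"
            )
        c = ex_names.index(e)
        for u in range(n_units):
            chosen = pool[rng.permutation(len(pool))[: len(split_ids)]]
            counts[split_ids, c, u, :] = counts_all[u, chosen, :]
    return Pseudopopulation(
        counts=counts, labels=labels, class_names=list(class_names), bin_starts=binned.bin_starts
    )


# ------------------------------------------------------------------- PNB
def pnb_train(counts: np.ndarray, classes: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Per-unit, per-class Poisson means from training data points.

    ``counts`` is (n_points, n_units), ``classes`` the class index of
    each point.  Means are floored at ``eps`` (default 1/(2 n_points))
    so that no class ever has a -inf log-likelihood.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("PNB requires nonnegative counts (z-scored inputs are invalid)")
    n_classes = int(classes.max()) + 1
    if eps is None:
        eps = 1.0 / (2 * len(counts))
    lam = np.stack([counts[classes == c].mean(axis=0) for c in range(n_classes)])
    return np.maximum(lam, eps)


def pnb_log_likelihood(lam: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Poisson log-likelihood scores up to the count-only constant.

    score(c) = sum_u (x_u log lam_cu - lam_cu); ``x`` may be (n_units,)
    or (n_points, n_units).
    """
    x = np.atleast_2d(x)
    return x @ np.log(lam).T - lam.sum(axis=1)


def pnb_predict(lam: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Maximum-likelihood class per data point; ties go to the lowest index."""
    return np.argmax(pnb_log_likelihood(lam, x), axis=1)


@dataclass
class AccuracyMatrix:
    """Train-bin x test-bin decoding accuracy with its permutation null."""

    accuracy: np.ndarray
    bin_starts: np.ndarray
    class_names: list[str]
    null_diagonals: np.ndarray | None = None
    significant_mask: np.ndarray | None = None

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)

    def onset_s(self) -> float | None:
        """Start time of the first significant bin, if any."""
        if self.significant_mask is None or not self.significant_mask.any():
            return None
        return float(self.bin_starts[np.argmax(self.significant_mask)])


def _decode_once(
    pop: Pseudopopulation, generalize: bool = True
) -> np.ndarray:
    """Leave-one-split-out accuracy; (n_bins, n_bins) or diagonal-only."""
    S, C, U, B = pop.counts.shape
    n_classes = len(pop.class_names)
    eps = 1.0 / (2 * (S - 1) * C)
    X = pop.counts.astype(float)
    lab = pop.labels
    # class sums over all splits, per bin
    sums = np.zeros((n_classes, U, B))
    npts = np.zeros(n_classes)
    for c in range(n_classes):
        m = lab == c
        sums[c] = X[m].sum(axis=0)
        npts[c] = m.sum()
    correct = np.zeros((B, B))
    total = 0
    for s in range(S):
        fold_sums = np.zeros((n_classes, U, B))
        fold_n = np.zeros(n_classes)
        for c in range(n_classes):
            m = lab[s] == c
            if m.any():
                fold_sums[c] = X[s, m].sum(axis=0)
                fold_n[c] = m.sum()
        train_n = npts - fold_n
        if (train_n == 0).any():
            raise ValueError("a class has no training points in some fold")
        lam = np.maximum(
            (sums - fold_sums) / train_n[:, None, None], eps
        )  # (classes, units, bins)
        loglam = np.log(lam)
        lamsum = lam.sum(axis=1)  # (classes, bins)
        Xs = X[s]  # (C, U, B)
        if generalize:
            scores = np.einsum("cub,kud->cdkb", Xs, loglam) - lamsum.T[None, :, :, None]
            # scores: (point, train_bin, class, test_bin)
            pred = scores.argmax(axis=2)  # (point, train_bin, test_bin)
            correct += (pred == lab[s][:, None, None]).sum(axis=0).astype(float)
        else:
            scores = np.einsum("cub,kub->cbk", Xs, loglam) - lamsum.T[None, :, :]
            pred = scores.argmax(axis=2)  # (point, bin)
            d = (pred == lab[s][:, None]).sum(axis=0).astype(float)
            correct += np.diag(d)
        total += C
    acc = correct / total
    return acc if generalize else np.diag(acc).copy()


def decode_factor(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    class_factor: str = "exemplar",
    n_runs: int = 50,
    seed: int = 0,
    formats: list[str] | None = None,
    generalize: bool = True,
) -> AccuracyMatrix:
    """Cross-validated decoding averaged over `n_runs` resample runs."""
    acc = None
    class_names = None
    for r in range(n_runs):
        pop = build_pseudopopulation(
            binned, trials, class_factor=class_factor, seed=int(substream(seed, 19, r).integers(2**31)), formats=formats
        )
        class_names = pop.class_names
        a = _decode_once(pop, generalize=generalize)
        acc = a if acc is None else acc + a
    acc = acc / n_runs
    if not generalize:
        acc = np.diag(acc)
    return AccuracyMatrix(accuracy=acc, bin_starts=binned.bin_starts, class_names=class_names)


def permutation_null(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    class_factor: str = "exemplar",
    n_runs: int = 50,
    n_shuffles: int = 50,
    seed: int = 0,
    formats: list[str] | None = None,
    min_run: int = 4,
) -> AccuracyMatrix:
    """Real decoding plus a label-shuffled null and significance mask.

    Labels are shuffled across trials before pseudopopulation assembly;
    a bin is significant when the real diagonal accuracy exceeds every
    one of the `n_shuffles` null accuracies, and only runs of at least
    `min_run` consecutive significant bins are retained.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle for a null distribution")
    real = decode_factor(
        binned, trials, class_factor, n_runs=n_runs, seed=seed, formats=formats, generalize=True
    )
    shuffle_cols = {
        "exemplar": ["exemplar"],
        "viewpoint": ["viewpoint"],
        "posture": ["posture"],
    }[class_factor]
    nulls = np.zeros((n_shuffles, len(binned.bin_starts)))
    for k in range(n_shuffles):
        rng = substream(seed, 23, k)
        shuffled = trials.copy()
        perm = rng.permutation(len(trials))
        for col in shuffle_cols:
            shuffled[col] = trials[col].to_numpy()[perm]
        a = decode_factor(
            binned, shuffled, class_factor, n_runs=1,
            seed=int(rng.integers(2**31)), formats=formats, generalize=False,
        )
        nulls[k] = a.diagonal
    diag = real.diagonal
    mask = consecutive_runs_mask(diag > nulls.max(axis=0), min_run)
    return AccuracyMatrix(
        accuracy=real.accuracy,
        bin_starts=binned.bin_starts,
        class_names=real.class_names,
        null_diagonals=nulls,
        significant_mask=mask,
    )


def cross_format_decode(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    train_format: str,
    test_format: str,
    n_runs: int = 50,
    seed: int = 0,
) -> AccuracyMatrix:
    """Train OMA decoding in one format, test in another.

    The model is trained on all splits of the training format's
    pseudopopulation and tested on every data point of the test
    format's.  Training and testing in the same format redirects to
    within-format cross-validated decoding.
    """
    if train_format == test_format:
        log.info("train and test format identical; running within-format cross-validation")
        return decode_factor(
            binned, trials, "exemplar", n_runs=n_runs, seed=seed,
            formats=[train_format], generalize=False,
        )
    B = len(binned.bin_starts)
    acc = np.zeros(B)
    for r in range(n_runs):
        rtr = substream(seed, 29, r)
        pop_tr = build_pseudopopulation(
            binned, trials, "exemplar", seed=int(rtr.integers(2**31)), formats=[train_format]
        )
        pop_te = build_pseudopopulation(
            binned, trials, "exemplar", seed=int(rtr.integers(2**31)), formats=[test_format]
        )
        S, C, U, _ = pop_tr.counts.shape
        eps = 1.0 / (2 * S * C)
        for b in range(B):
            Xtr = pop_tr.counts[:, :, :, b].reshape(-1, U).astype(float)
            ytr = pop_tr.labels.reshape(-1)
            lam = pnb_train(Xtr, ytr, eps=eps)
            Xte = pop_te.counts[:, :, :, b].reshape(-1, U).astype(float)
            yte = pop_te.labels.reshape(-1)
            acc[b] += (pnb_predict(lam, Xte) == yte).mean()
    acc /= n_runs
    return AccuracyMatrix(
        accuracy=np.diag(acc), bin_starts=binned.bin_starts, class_names=list(EXEMPLARS)
    )


# ------------------------------------------------- z-scored alternative
def correlation_decode_once(pop: Pseudopopulation) -> np.ndarray:
    """Leave-one-split-out accuracy of a z-scored correlation classifier.

    Normalization parameters come from the training splits only; each
    test point is assigned the class whose normalized training mean it
    correlates with best.  Diagonal (per-bin) accuracy only.
    """
    S, C, U, B = pop.counts.shape
    n_classes = len(pop.class_names)
    X = pop.counts.astype(float)
    correct = np.zeros(B)
    for s in range(S):
        m_train = np.ones(S, dtype=bool)
        m_train[s] = False
        Xtr = X[m_train].reshape(-1, U, B)
        ytr = pop.labels[m_train].reshape(-1)
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        proto = np.stack(
            [((Xtr[ytr == c] - mu) / sd).mean(axis=0) for c in range(n_classes)]
        )  # (classes, U, B)
        Z = (X[s] - mu) / sd  # (C, U, B)
        for b in range(B):
            zc = Z[:, :, b] - Z[:, :, b].mean(axis=1, keepdims=True)
            pc = proto[:, :, b] - proto[:, :, b].mean(axis=1, keepdims=True)
            num = zc @ pc.T
            den = np.sqrt((zc**2).sum(1))[:, None] * np.sqrt((pc**2).sum(1))[None, :]
            den[den == 0] = 1.0
            pred = (num / den).argmax(axis=1)
            correct[b] += (pred == pop.labels[s]).sum()
    return correct / (S * C)
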