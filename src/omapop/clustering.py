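"""Mahalanobis-distance clustering of conditions in neural state space.

A population firing-rate matrix F (N units x c conditions x t time
points, trial-averaged) defines, for each condition, a cloud of t points
in the N-dimensional state space.  Pairwise condition distances are
Mahalanobis distances under the pooled within-condition covariance
(ridge-regularized: with hundreds of units and few time samples the
pooled covariance is singular), divided by N so that the statistic does
not grow with population size.  The distance matrix feeds average-
linkage (UPGMA) agglomeration with optimal leaf ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import EXEMPLARS, FORMATS
from .recording import BinnedTensor


def condition_distances(
    F: np.ndarray, ridge_gamma: float = 0.1
) -> np.ndarray:
    """Normalized Mahalanobis distance between all condition pairs.

    ``F`` is (N units, c conditions, t time points).  The pooled
    within-condition covariance W of the time-point clouds is shrunk as
    W + gamma * trace(W)/N * I before inversion; the distance
    sqrt((mu_a - mu_b)' W^-1 (mu_a - mu_b)) is divided by N.
    """
    F = np.asarray(F, dtype=float)
    n_units, n_cond, n_t = F.shape
    if n_t < 2:
        raise ValueError("need at least two time points per condition; bin more finely")
    mu = F.mean(axis=2)  # (N, c)
    centred = F - mu[:, :, None]
    W = np.einsum("uct,vct->uv", centred, centred) / (n_cond * (n_t - 1))
    W = W + ridge_gamma * np.trace(W) / n_units * np.eye(n_units)
    Winv_mu = np.linalg.solve(W, mu)
    D = np.zeros((n_cond, n_cond))
    for a in range(n_cond):
        for b in range(a + 1, n_cond):
            d = mu[:, a] - mu[:, b]
            val = float(d @ (Winv_mu[:, a] - Winv_mu[:, b]))
            D[a, b] = D[b, a] = np.sqrt(max(val, 0.0)) / n_units
    return D


@dataclass
class ClusterTree:
    """Average-linkage tree over conditions with optimal leaf order."""

    distances: np.ndarray
    linkage: np.ndarray
    leaf_order: np.ndarray
    labels: list[str]

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            # ultrametric convention: a node sits at half its merge height
            la = h / 2 - heights[a] / 2
            lb = h / 2 - heights[b] / 2
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def build_tree(distances: np.ndarray, labels: list[str] | None = None) -> ClusterTree:
    """UPGMA tree from a symmetric distance matrix, leaves optimally ordered."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = labels or [str(i) for i in range(D.shape[0])]
    cond = squareform(D, checks=False)
    Z = hierarchy.linkage(cond, method="average")
    Z = hierarchy.optimal_leaf_ordering(Z, cond)
    order = hierarchy.leaves_list(Z)
    return ClusterTree(distances=D, linkage=Z, leaf_order=order, labels=labels)


def state_space_matrix(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    mode: str = "format_independent",
    window: tuple[float, float] = (0.0, 1.5),
) -> tuple[np.ndarray, list[str]]:
    """Trial-averaged F (N x c x t) over the epoch of interest.

    ``format_independent`` pools the four formats into c = 7 exemplar
    conditions; ``format_dependent`` keeps c = 28 exemplar x format
    conditions.
    """
    in_win = (binned.bin_starts >= window[0] - 1e-9) & (
        binned.bin_starts + binned.bin_width_s <= window[1] + 1e-9
    )
    if in_win.sum() < 2:
        raise ValueError("epoch of interest covers fewer than two bins")
    rates = binned.rates[:, :, in_win]
    if mode == "format_independent":
        conds = [(e, None) for e in EXEMPLARS]
        labels = list(EXEMPLARS)
    elif mode == "format_dependent":
        conds = [(e, f) for f in FORMATS for e in EXEMPLARS]
        labels = [f"{e}|{f}" for f in FORMATS for e in EXEMPLARS]
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    F = np.zeros((rates.shape[0], len(conds), in_win.sum()))
    for c, (e, f) in enumerate(conds):
        m = (trials["exemplar"] == e).to_numpy()
        if f is not None:
            m &= (trials["format"] == f).to_numpy()
        if not m.any():
            raise ValueError(f"no trials for condition {e}/{f}")
        F[:, c, :] = rates[:, m, :].mean(axis=1)
    return F, labels


def cluster_exemplars(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    mode: str = "format_independent",
    window: tuple[float, float] = (0.0, 1.5),
    ridge_gamma: float = 0.1,
) -> ClusterTree:
    """Cluster OMA exemplars (optionally per format) in neural state space."""
    F, labels = state_space_matrix(binned, trials, mode=mode, window=window)
    D = condition_distances(F, ridge_gamma=ridge_gamma)
    return build_tree(D, labels)
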