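"""Vectorized repeated-measures ANOVA machinery.

The unit-classification screens run thousands of small ANOVAs with the
same balanced layout (trials as subjects, epoch as the within-subject
factor, exemplar or video as the between-subject factor), so the
split-plot sums of squares are computed in closed form and vectorized
across units rather than dispatched one model at a time.  Results agree
with `pingouin.mixed_anova` on the same data (see the test suite).

Within-subject F tests can be Greenhouse-Geisser corrected.  The epoch
windows have different durations, so under Poisson firing the epoch-wise
rate variances differ and sphericity cannot be assumed; the correction
keeps the within-subject tests calibrated and is on by default.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _gg_epsilon(pooled_cov: np.ndarray) -> np.ndarray:
    """Greenhouse-Geisser epsilon from (..., p, p) within-subject covariances."""
    p = pooled_cov.shape[-1]
    diag_mean = np.trace(pooled_cov, axis1=-2, axis2=-1) / p
    grand = pooled_cov.mean(axis=(-2, -1))
    row = pooled_cov.mean(axis=-1)
    num = (p * (diag_mean - grand)) ** 2
    den = (p - 1) * (
        (pooled_cov**2).sum(axis=(-2, -1))
        - 2 * p * (row**2).sum(axis=-1)
        + p**2 * grand**2
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        eps = num / den
    return np.clip(np.nan_to_num(eps, nan=1.0), 1.0 / (p - 1), 1.0)


def split_plot_anova(
    y: np.ndarray,
    groups: np.ndarray,
    gg_correction: bool = True,
) -> dict[str, np.ndarray]:
    """Balanced split-plot (mixed) ANOVA, vectorized over leading axes.

    Parameters
    ----------
    y
        ``(..., n_subjects, p)`` responses; subjects (trials) carry `p`
        repeated measures (the within factor levels).
    groups
        ``(n_subjects,)`` integer codes of the between factor; the design
        must be balanced (equal subjects per group).
    gg_correction
        Apply the Greenhouse-Geisser sphericity correction to the within
        and interaction tests.

    Returns
    -------
    dict with ``F_between, p_between, F_within, p_within, F_interaction,
    p_interaction`` arrays of shape ``y.shape[:-2]``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels, codes = np.unique(groups, return_inverse=True)
    g = len(levels)
    n_subj, p = y.shape[-2], y.shape[-1]
    counts = np.bincount(codes)
    if not (counts == counts[0]).all():
        raise ValueError("split_plot_anova requires a balanced between factor")
    n = counts[0]
    if n < 2:
        raise ValueError("at least two subjects per group required")

    grand = y.mean(axis=(-2, -1), keepdims=True)
    subj_mean = y.mean(axis=-1)  # (..., n_subj)
    within_mean = y.mean(axis=-2)  # (..., p)

    # group means: (..., g) and cell means (..., g, p)
    onehot = np.eye(g)[codes]  # (n_subj, g)
    group_mean = np.einsum("...sp,sg->...g", y, onehot) / (n * p)
    cell_mean = np.einsum("...sp,sg->...gp", y, onehot) / n

    gm = grand[..., 0, 0]
    ss_between_subj = p * ((subj_mean - gm[..., None]) ** 2).sum(axis=-1)
    ss_groups = p * n * ((group_mean - gm[..., None]) ** 2).sum(axis=-1)
    ss_subj = ss_between_subj - ss_groups
    ss_within = n_subj * ((within_mean - gm[..., None]) ** 2).sum(axis=-1)
    inter_dev = (
        cell_mean
        - group_mean[..., :, None]
        - within_mean[..., None, :]
        + gm[..., None, None]
    )
    ss_inter = n * (inter_dev**2).sum(axis=(-2, -1))
    ss_total = ((y - grand) ** 2).sum(axis=(-2, -1))
    ss_err_within = ss_total - ss_between_subj - ss_within - ss_inter

    df_groups, df_subj = g - 1, g * (n - 1)
    df_within, df_inter = p - 1, (g - 1) * (p - 1)
    df_err_within = g * (n - 1) * (p - 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_between = (ss_groups / df_groups) / (ss_subj / df_subj)
        f_within = (ss_within / df_within) / (ss_err_within / df_err_within)
        f_inter = (ss_inter / df_inter) / (ss_err_within / df_err_within)

    if gg_correction:
        resid = y - cell_mean[..., codes, :]
        pooled = np.einsum("...sp,...sq->...pq", resid, resid) / (n_subj - g)
        eps = _gg_epsilon(pooled)
    else:
        eps = np.ones(y.shape[:-2])

    p_between = stats.f.sf(f_between, df_groups, df_subj)
    p_within = stats.f.sf(f_within, eps * df_within, eps * df_err_within)
    p_inter = stats.f.sf(f_inter, eps * df_inter, eps * df_err_within)
    return {
        "F_between": f_between,
        "p_between": p_between,
        "F_within": f_within,
        "p_within": p_within,
        "F_interaction": f_inter,
        "p_interaction": p_inter,
        "gg_epsilon": eps,
    }


def one_way_anova(samples: list[np.ndarray], axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """One-way fixed-effects ANOVA across groups, vectorized on `axis`."""
    res = stats.f_oneway(*samples, axis=axis)
    return res.statistic, res.pvalue


def rm_one_way_anova(y: np.ndarray, gg_correction: bool = True) -> dict[str, float]:
    """One-way repeated-measures ANOVA; ``y`` is (n_subjects, p)."""
    y = np.asarray(y, dtype=float)
    n, p = y.shape
    gm = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    ss_cond = n * ((cond_mean - gm) ** 2).sum()
    ss_subj = p * ((subj_mean - gm) ** 2).sum()
    ss_total = ((y - gm) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = p - 1, (n - 1) * (p - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    if gg_correction:
        centred = y - subj_mean[:, None]
        pooled = np.einsum("sp,sq->pq", centred, centred) / (n - 1)
        eps = float(_gg_epsilon(pooled))
    else:
        eps = 1.0
    pval = float(stats.f.sf(f, eps * df_cond, eps * df_err))
    return {"F": float(f), "p": pval, "df1": df_cond, "df2": df_err, "gg_epsilon": eps}
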