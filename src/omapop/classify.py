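"""ANOVA-based unit classification and the motion/contrast screen.

Main experiment: per format, a 3 x 7 mixed ANOVA (epoch within-trial:
baseline / epoch 1 / epoch 2; exemplar between-trial) classifies units as
task-unrelated, action-related (epoch effect in at least one format,
confirmed by a Bonferroni post hoc against baseline) or OMA-selective
(additionally an exemplar main or interaction effect).

Control experiment: a 2 x 9 mixed ANOVA (epoch within-trial; video
between-trial) with a Fisher LSD post hoc classifies units as
unresponsive, video-related or video-selective, and a Pearson screen
across the nine per-video mean rates flags units whose firing tracks the
motion (or contrast) covariate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .anova import one_way_anova, rm_one_way_anova, split_plot_anova
from .design import EXEMPLARS, EpochWindows, FORMATS
from .recording import BinnedTensor, RecordingSet, epoch_rates

log = logging.getLogger(__name__)

MAIN_EPOCH_ORDER = ("baseline", "epoch1", "epoch2")


def _epoch_cube(
    recordings: RecordingSet, epoch_names: tuple[str, ...], windows: dict
) -> tuple[np.ndarray, pd.DataFrame]:
    """(n_units, n_trials, n_epochs) rate array in trial-table order."""
    from .recording import _count_in_windows

    ordered = [windows[k] for k in epoch_names]
    counts, _, _ = _count_in_windows(recordings, ordered)
    widths = np.array([hi - lo for lo, hi in ordered])
    return counts / widths, recordings.trials


def classify_main(
    recordings: RecordingSet,
    alpha: float = 0.05,
    epochs: EpochWindows | None = None,
    gg_correction: bool = True,
) -> pd.DataFrame:
    """Classify every unit of a main session.

    Returns one row per unit: ``main_label`` in {task_unrelated,
    action_related, oma_selective}, the formats with a significant
    exemplar effect (``selective_formats``, semicolon-joined) and the
    per-format ANOVA and post hoc P-values.
    """
    epochs = epochs or EpochWindows()
    cube, trials = _epoch_cube(recordings, MAIN_EPOCH_ORDER, epochs.main())
    ex_codes = trials["exemplar"].map({e: i for i, e in enumerate(EXEMPLARS)}).to_numpy()

    rows = {"unit_id": recordings.unit_ids}
    epoch_sig = np.zeros((len(recordings.units), len(FORMATS)), dtype=bool)
    exemplar_sig = np.zeros_like(epoch_sig)
    for j, fmt in enumerate(FORMATS):
        sel = (trials["format"] == fmt).to_numpy()
        y = cube[:, sel, :]
        if np.bincount(ex_codes[sel]).min() == 0:
            raise ValueError(f"format {fmt}: an exemplar has no trials")
        flat = y.var(axis=(1, 2)) == 0
        res = split_plot_anova(y, ex_codes[sel], gg_correction=gg_correction)
        if flat.any():
            log.info("%d zero-variance unit(s) in %s classified task_unrelated", flat.sum(), fmt)
            for k in res:
                res[k] = np.where(flat, np.nan, res[k])
        # Bonferroni post hoc: either video epoch differs from baseline
        t1 = stats.ttest_rel(y[:, :, 1], y[:, :, 0], axis=1)
        t2 = stats.ttest_rel(y[:, :, 2], y[:, :, 0], axis=1)
        p_post = np.minimum(1.0, 2 * np.fmin(t1.pvalue, t2.pvalue))
        epoch_eff = np.fmin(res["p_within"], res["p_interaction"]) < alpha
        epoch_sig[:, j] = epoch_eff & (p_post < alpha)
        exemplar_sig[:, j] = np.fmin(res["p_between"], res["p_interaction"]) < alpha
        rows[f"p_epoch_{fmt}"] = res["p_within"]
        rows[f"p_exemplar_{fmt}"] = res["p_between"]
        rows[f"p_interaction_{fmt}"] = res["p_interaction"]
        rows[f"p_posthoc_{fmt}"] = p_post

    action = epoch_sig.any(axis=1)
    selective = action & exemplar_sig.any(axis=1)
    label = np.where(selective, "oma_selective", np.where(action, "action_related", "task_unrelated"))
    sel_formats = [
        ";".join(f for f, s in zip(FORMATS, exemplar_sig[i]) if s) if selective[i] else ""
        for i in range(len(label))
    ]
    out = pd.DataFrame(rows)
    out.insert(1, "main_label", label)
    out.insert(2, "selective_formats", sel_formats)
    return out


def classify_control(
    recordings: RecordingSet,
    alpha: float = 0.05,
    epochs: EpochWindows | None = None,
    gg_correction: bool = True,
) -> pd.DataFrame:
    """Classify control-session units as unresponsive / video_related /
    video_selective via the 2 x 9 mixed ANOVA with a Fisher LSD gate."""
    epochs = epochs or EpochWindows()
    cube, trials = _epoch_cube(recordings, ("baseline", "video"), epochs.control())
    vid_codes = trials["video"].to_numpy()
    res = split_plot_anova(cube, vid_codes, gg_correction=gg_correction)
    flat = cube.var(axis=(1, 2)) == 0
    if flat.any():
        log.info("%d zero-variance control unit(s) labelled unresponsive", flat.sum())
        for k in res:
            res[k] = np.where(flat, np.nan, res[k])
    # Fisher LSD on the epoch contrast: unadjusted paired t, gated on the omnibus
    t = stats.ttest_rel(cube[:, :, 1], cube[:, :, 0], axis=1)
    epoch_eff = np.fmin(res["p_within"], res["p_interaction"]) < alpha
    related = epoch_eff & (t.pvalue < alpha)
    video_eff = np.fmin(res["p_between"], res["p_interaction"]) < alpha
    selective = related & video_eff
    label = np.where(selective, "video_selective", np.where(related, "video_related", "unresponsive"))
    return pd.DataFrame(
        {
            "unit_id": recordings.unit_ids,
            "control_label": label,
            "p_epoch": res["p_within"],
            "p_video": res["p_between"],
            "p_interaction": res["p_interaction"],
            "p_lsd_epoch": t.pvalue,
        }
    )


def per_video_rates(
    recordings: RecordingSet, epochs: EpochWindows | None = None
) -> pd.DataFrame:
    """Per-unit mean video-epoch rate for each of the nine control videos."""
    epochs = epochs or EpochWindows()
    tidy = epoch_rates(recordings, {"video": epochs.control_video})
    merged = tidy.merge(recordings.trials[["trial_id", "video"]], on="trial_id")
    return (
        merged.groupby(["unit_id", "video"], sort=True)["rate"].mean().unstack("video")
    )


def motion_contrast_screen(
    recordings: RecordingSet,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    epochs: EpochWindows | None = None,
) -> pd.DataFrame:
    """Pearson screen of per-video mean rate against motion and contrast.

    A unit is flagged ``excluded_for_motion`` when the correlation of its
    nine video-epoch mean rates with the motion covariate is significant.
    """
    rates = per_video_rates(recordings, epochs)
    cov = covariates.sort_values("video")
    rows = []
    for unit_id, r in rates.iterrows():
        r = r.to_numpy()
        if np.ptp(r) == 0:
            log.info("unit %s: zero-variance video rates, correlation undefined", unit_id)
            rows.append((unit_id, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rm, pm = stats.pearsonr(r, cov["motion"].to_numpy())
        rc, pc = stats.pearsonr(r, cov["contrast"].to_numpy())
        rows.append((unit_id, rm, pm, rc, pc, pm < alpha))
    return pd.DataFrame(
        rows,
        columns=["unit_id", "r_motion", "p_motion", "r_contrast", "p_contrast", "excluded_for_motion"],
    )


def population_video_preference(
    per_unit_video_rates: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Population-level preference across the nine control videos.

    Units are the repeated measures; a one-way repeated-measures ANOVA
    across videos is followed by Bonferroni-corrected pairwise paired
    t-tests.  ``per_unit_video_rates`` is units x videos.
    """
    y = np.asarray(per_unit_video_rates, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("population preference needs at least two units")
    omnibus = rm_one_way_anova(y)
    n_vid = y.shape[1]
    pairs = []
    n_comp = n_vid * (n_vid - 1) // 2
    for a in range(n_vid):
        for b in range(a + 1, n_vid):
            t = stats.ttest_rel(y[:, a], y[:, b])
            pairs.append((a, b, t.statistic, min(1.0, t.pvalue * n_comp)))
    pairwise = pd.DataFrame(pairs, columns=["video_a", "video_b", "t", "p_bonf"])
    pairwise["significant"] = (pairwise["p_bonf"] < alpha) & (omnibus["p"] < alpha)
    return {"omnibus": omnibus, "means": y.mean(axis=0), "pairwise": pairwise}


def tuned_fraction_timecourse(
    binned: BinnedTensor,
    trials: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of units tuned to `factor` in each sliding bin.

    Per bin and unit, a one-way ANOVA across the factor levels on the
    single-trial rates; the per-bin fraction of units with P < alpha is
    tested against the mean pre-onset (baseline) fraction with a 2 x 2
    chi-square.  Returns ``(bin_start, fraction, p_chi2, significant)``.
    """
    levels = trials[factor].unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two levels")
    samples = [
        binned.rates[:, (trials[factor] == lv).to_numpy(), :] for lv in levels
    ]
    _, pvals = one_way_anova(samples, axis=1)  # (units, bins)
    tuned = pvals < alpha
    n_units = tuned.shape[0]
    fraction = tuned.mean(axis=0)
    base = binned.bin_starts + binned.bin_width_s <= 1e-9
    if not base.any():
        raise ValueError("no baseline bins available for the chi-square reference")
    k_base = int(round(tuned[:, base].sum(axis=0).mean()))
    p_chi2 = np.ones(len(binned.bin_starts))
    for b in range(len(binned.bin_starts)):
        k = int(tuned[:, b].sum())
        table = np.array([[k, n_units - k], [k_base, n_units - k_base]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            continue
        p_chi2[b] = stats.chi2_contingency(table)[1]
    return pd.DataFrame(
        {
            "bin_start": binned.bin_starts,
            "fraction": fraction,
            "p_chi2": p_chi2,
            "significant": p_chi2 < alpha,
        }
    )


def preference_index(condition_means: np.ndarray) -> float:
    """Selectivity depth over condition means: 0 = flat, 1 = one-hot.

    PI = (n - sum_i m_i / m_max) / (n - 1).
    """
    m = np.asarray(condition_means, dtype=float)
    n = m.size
    if m.max() <= 0:
        return 0.0
    return float((n - (m / m.max()).sum()) / (n - 1))
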