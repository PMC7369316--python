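# Methods

## The analysis problem

A session presents videos of seven observed manipulative actions
(OMAs) in four visual formats — actor posture (standing / sitting)
crossed with camera viewpoint (lateral / frontal) — with actor
identity, target object and three repetitions as additional variation:
7 x 4 x 2 x 2 x 3 = 336 trials, 12 per OMA x format cell. Spiking is
aligned to video onset (t = 0) with a 500-ms baseline and a 2.6-s
video; analysis epochs are epoch 1 = [0, 0.3) s (static posture cues)
and epoch 2 = [0.3, 1.5) s (the dynamic action). A control session
shows nine natural videos (3.5 s, 10 trials each) with per-video
motion and contrast covariates; its response epoch is [0.5, 3.0) s.
All bins are half-open `[start, start + width)` and are reported at
the start of their interval.

## Synthetic data generator

The generator is the test bed for every downstream stage: each unit
carries a generative class that fixes how format and exemplar
information combine in its expected epoch-2 rate.

| class | epoch-2 expectation |
|---|---|
| `multiplicative_stable` | baseline + gain_j · tuning_i |
| `additive` | baseline + gain_j + tuning_i |
| `mixed_unstable` | baseline + tuning_{j,i} (independent per format) |
| `format_only` | baseline + gain_j |
| `untuned` | baseline |
| `motion_coupled` (control) | baseline + slope · motion_v |

Temporal structure separates a *static* format component (a step over
the whole video) from a *dynamic* action component that ramps linearly
from 0.3 s to 1.5 s and then holds; the ramp peaks at twice its nominal
amplitude so its epoch-2 *mean* equals the nominal value and the table
above holds exactly as epoch-2 expectations. Actor and object identity
add a small static zero-mean rate offset during the video (default 5%
of the unit's tuning amplitude), emulating the residual visual
variability of the four video variants per cell. Spikes are drawn by
thinning an inhomogeneous Poisson process at 1-ms rate resolution; each
unit gets an independent counter-keyed Philox substream of the session
seed, so identical seeds give byte-identical spike tables and any unit
can be regenerated alone.

Default parameters (chosen once; units spikes/s): spontaneous rate
uniform on 1–5, typical of visually driven parietal units at rest;
exemplar tuning a randomly permuted graded-preference profile
`exp(-rank)` peaking at 25, i.e. a clear best action with exponential
fall-off; multiplicative format gains uniform on 0.6–1.6 (rate
rescaling without rank changes); additive/format-only offsets a sparse
permuted profile peaking at 20. The modulation-to-baseline ratio
matters beyond realism: an identifiability analysis during design
showed that when a 4 x 7 rate matrix is dominated by a constant
component (high baseline, dense tuning), its best rank-1 approximation
reproduces *any* outer-sum structure to second order while the
no-intercept additive regression trades pattern correlation for offset
fit — purely additive units would then be indistinguishable from
multiplicative ones by construction, defeating the generator's purpose
as a recovery test bed. Responses several-fold above a low spontaneous
rate, with sparse preference profiles, put both classes in the regime
where each model wins on its own data.

What the generator does not emulate: spike-train autocorrelation and
refractoriness (counts are exactly Poisson), slow drifts and session
nonstationarity, correlated noise across units (pseudopopulations built
from it are "noise-correlation-free" by construction, as real
pseudopopulations are by assembly), and realistic kinematics within the
video (the ramp is a single shared envelope). Passing recovery tests
therefore demonstrates correctness of the analysis code under the
stated statistical assumptions, not robustness to these real-data
features.

## Unit classification

Per format, a 3 x 7 split-plot ANOVA with epoch (baseline / epoch 1 /
epoch 2) as the within-trial factor and exemplar as the between-trial
factor; trials are the replicates. A unit is *action-related* if the
epoch factor is significant (P < 0.05, main or interaction) in at least
one format and a Bonferroni-corrected paired post hoc confirms that
epoch 1 and/or epoch 2 differs from baseline; *OMA-selective* if the
exemplar factor (main or interaction) is additionally significant. The
control session uses the analogous 2 x 9 design with a Fisher LSD gate
(unadjusted pairwise t conditional on the omnibus). Because the epoch
windows have different durations, Poisson rate variances differ across
epochs and sphericity cannot hold; within-subject tests are therefore
Greenhouse–Geisser corrected by default, which keeps their false-
positive rate at the nominal 5% (verified on 1000 null units). The
ANOVA sums of squares are computed in closed form and vectorized across
units; the implementation is checked against `pingouin.mixed_anova` in
the test suite.

The motion/contrast screen correlates each unit's nine per-video mean
rates with the motion and contrast covariates (Pearson, n = 9) and
flags units with a significant motion correlation. A preference index
`PI = (n − Σ λ_i/λ_max)/(n − 1)` over condition means (0 = flat,
1 = one-hot) is provided for selectivity-depth summaries; its exact
form is this package's choice.

The tuned-fraction time course runs a one-way ANOVA per 150-ms bin
(50-ms steps) across the levels of a chosen factor and tests each bin's
tuned fraction against the mean pre-onset fraction with a 2 x 2
chi-square, where the baseline reference count is the rounded mean
tuned count over fully pre-onset bins.

## Mixing models

For each unit, trials of every cell are split into halves (even/odd
presentation order, or random with a seed). From the training half O′:
additive prediction `A_ij = k1 E_i + k2 F_j` with E = column means,
F = row means and (k1, k2) by ordinary least squares over the 28 cells
with no intercept (exactly two constants; a flag allows estimating them
against the held-out half instead — the default keeps the fit
self-contained on the training half); multiplicative prediction
`M = s1 u1 v1ᵀ`, the leading rank-1 SVD reconstruction, unique whenever
s1 > s2 since the sign ambiguity cancels in the product. A, M and O′
itself (the split-half reliability ceiling) are each scored by squared
Pearson correlation with the held-out matrix O; correlation is
offset- and sign-blind, which is documented behavior. Population
comparison uses medians and two-sided Mann–Whitney U tests
(tie-corrected normal Z; exact null below n = 8 per group). The
time-resolved variant repeats random-split fitting in 150-ms/50-ms
windows 20 times, averages per unit, and compares the three series with
sliding Wilcoxon signed-rank tests, reporting only runs of at least
four consecutive significant windows.

## Pseudopopulation decoding

Binned counts (150-ms bins, 50-ms steps by convention; the bin width
converts rates back to integer counts) are assembled into
pseudopopulation data points: per condition, each unit contributes one
randomly chosen trial per split. Format-independent OMA decoding pools
48 trials per exemplar into 48 splits of 7 points (336 data points);
single-format OMA decoding gives 12 x 7 = 84; viewpoint/posture
decoding keeps the seven exemplars as the split-structure conditions,
with half the 24 splits carrying each level (24 x 7 = 168 points, 12 of
the 24 trials per exemplar x level cell used per resample run). The
Poisson naive Bayes classifier estimates per-unit, per-class mean
counts λ from the training splits (floored at 1/(2 n_train) so no
log-likelihood is −∞) and assigns the class maximizing
`Σ_u n_u log λ_uc − λ_uc`; ties go to the lowest class index. Raw
counts feed the classifier — Poisson likelihoods require nonnegative
integers — and a z-scored correlation classifier (normalization
parameters from training splits only) is provided as the
rate-normalized alternative. Leave-one-split-out cross-validation over
all splits, averaged over 50 resample runs, fills the train-bin x
test-bin generalization matrix. Chance is established by re-running the
whole procedure with labels shuffled before assembly (50 shuffles);
bins count as significant only where real accuracy exceeds *every*
null value in runs of ≥ 4 consecutive bins, and the onset is the start
of the first significant bin.

## Rank stability index

In 500-ms bins stepped by 20 ms, exemplars are ranked by trial-averaged
rate within each format (ties broken by fixed exemplar order). With a
reference format (default stand-lateral), `Rf_i` is the rank of the
reference format's best exemplar in test format i, and
`RSIr = 1 + Σ (1 − (1/7)(Rf_i − 1))` ∈ [10/7, 4] is normalized by
(max − min) onto [0, 1] — the only normalization consistent with a
0-to-1 range; exact enumeration of the 343 rank triples gives 19 evenly
spaced achievable values with mean exactly 1/2 under independent
uniform ranks. The exact fraction 10/7 = 1.42857… is authoritative in
code (its 4-decimal rounding is 1.4286). The unconstrained null redraws
every rank uniformly per bin; the constrained null applies one random
value map {1..7} → {1..7} per test format to all bins (sampled with
replacement, following the literal "a random integer value" rule; a
bijective variant is available), preserving the temporal structure of
rank changes. A unit's total score sums normalized RSI over bins lying
entirely within epochs 1 + 2 ([0, 1.5) s); sorting by total score and
labelling the top ⌊n/2⌋ units stable reproduces the 56/57 split at
n = 113. Being rank-based, the index is invariant to any strictly
monotone rescaling of rates within a format.

## State-space clustering

A population matrix F (N units x c conditions x t time points,
trial-averaged 60-ms/20-ms bins over epochs 1 + 2 by default; c = 7
exemplars or c = 28 exemplar x format) defines per-condition clouds of
t points in N-space. The pooled within-condition covariance W is
ridge-regularized as W + γ·trace(W)/N·I (default γ = 0.1) because N
typically exceeds c·t and W is otherwise singular; condition distances
are Mahalanobis under the regularized W, divided by N so the statistic
does not grow with population size. Average-linkage (UPGMA)
agglomeration with optimal leaf ordering yields the dendrogram;
distances are computed in the raw unit space (not a discriminant
projection), which is the documented choice.

## Numerical and design notes

- Problem sizes in the test suite: recovery properties run on 100-unit
  sessions over 50 seeds (mixing dissociation, RSI recovery), decoding
  contrasts on 12–40 unit sessions with late-video windows and 5
  resample runs, calibration on 1000 null units — sizes at which every
  targeted effect is decisively in or out of its noise band.
- Zero-variance units are excluded from ANOVA labels (task-unrelated),
  correlations (not excluded by the screen) and population r² medians,
  each with a log record.
- Degenerate additive designs (flat E and F) fall back to
  k1 = k2 = 0.5; all-zero training matrices give M = 0; tied leading
  singular values and rank ties are resolved deterministically and
  logged.
- The epoch-2 window is fixed at [0.3, 1.5) s for all exemplars; no
  per-exemplar action-end adjustment is attempted.
- Known limitations: the additive-vs-multiplicative contrast is
  informative only when responses are large relative to the shared
  constant component (see the generator identifiability note); the
  family-wise character of the "any format, main or interaction"
  selectivity rule gives exemplar-flat units a ~30% chance of a
  spurious selective label, an inherent property of the rule rather
  than a calibration error of the tests it composes.
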