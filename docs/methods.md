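# Methods

## The model

Two-block partial least squares (2B-PLS, also inter-battery factor
analysis; in morphometrics associated with Rohlf & Corti) relates two
matrices observed on the same objects.  Here the objects are eyes-open
trials; block B1 (n × p1) holds measured behavioural covariates, block
B2 (n × p2) binary experimental-design indicators.

Both blocks are column-centered and (by default) scaled to unit sample
variance.  The fit is a single SVD of the cross-product of the
preprocessed blocks,

    C = Z1ᵀ Z2 = U S Vᵀ,

giving K = min(p1, p2) latent structures.  Properties relied on
throughout:

* `U` and `V` have orthonormal columns ("orthogonal load matrices").
* Scores `T1 = Z1 U`, `T2 = Z2 V` have paired covariance
  `cov(t1ₖ, t2ₖ) = sₖ/(n−1)` — the first pair maximises that covariance
  over all unit weight vectors, each later pair maximises it subject to
  orthogonality of weights; the cross-covariance matrix `T1ᵀT2/(n−1)`
  is exactly diagonal.
* Variance shares are `sₖ² / Σⱼ sⱼ²` — the standard 2B-PLS scree
  quantity, i.e. the share of total squared cross-block covariance.
  (The source analyses report a "share of total variance" without a
  formula; this is the conventional reading.)
* The decomposition exists and is stable for p > n and for exactly
  collinear columns; zero singular values are legitimate output.

An iterative NIPALS-with-deflation fit would converge to the same
decomposition in this symmetric two-block case; the one-shot SVD is
used because it is deterministic and directly testable, and the choice
is recorded in the model's preprocessing metadata.

**Sign convention.**  Singular vectors are sign-indeterminate; each
axis pair is flipped so that the largest-magnitude element of the
block-1 weight vector is positive.  This makes fits, saved TSVs and
reruns byte-identical.

**Correlation loadings** are the Pearson correlations of each
*original* (un-preprocessed) variable with its own block's scores.
They are invariant to any rescaling of the scores, which sidesteps the
(unstated in most applied accounts) choice of score normalisation.
Variables or scores that are constant up to round-off get loading 0
plus an `undefined` flag.

**Significance.**  The default mask tests each loading r against the
null r = 0 with `t = r √((n−2)/(1−r²))`, n − 2 degrees of freedom,
two-sided; `critical_r(n, alpha)` inverts the relation to give the |r|
delimiting the significance rectangle on paired-loading plots
(0.1543 at n = 162, α = 0.05).  With trials as objects the n = 162
rows include repeated measures of 18 subjects, so the t-test's
independence assumption is optimistic; a permutation alternative
(`permutation_loading_pvalues`, row shuffling of block 2, 999
permutations by default, seeded) is provided.  Note that row shuffling
destroys the block *pairing* but not within-block structure, so the
permutation p-values for own-block loadings are conservative; the
permutation null of the *first variance share*
(`permutation_null_shares`) is the sharper global test of whether any
pairing exists at all.

## Feature extraction

* **AU range** = max − min of the per-frame AU intensity over the
  trial's QC-retained frames, in 0–5 intensity units.  The range is
  used instead of the mean or SD because two minutes of quiet sitting
  yields a fluctuation floor that dominates moments, while the
  discriminating signal is carried by excursions.  A spike confined to
  a QC-dropped frame cannot inflate the range.
* **Gaze-on-screen proportion** = fraction of retained frames with
  √(gaze_angle_x² + gaze_angle_y²) ≤ threshold.  Default threshold
  10° (0.1745 rad): roughly the half-angle a monitor subtends at
  webcam distance.  No standard numeric criterion exists; the value is
  a config knob and is recorded in output metadata.
* **Quality control.**  Frames are retained when the tracker reports
  success and confidence ≥ `min_confidence` (default 0.75, the
  conventional tracking cut; the study protocol lists behavioural
  exclusions but no numeric threshold).  A trial is flagged *excluded*
  — never silently dropped — when fewer than `min_frames` frames
  survive (default 300, ≈10 s at 30 fps) or when the retained fraction
  of its span falls below `min_retained` (default 0.5, the per-trial
  analogue of excluding a participant for instruction violations).
  Excluded trials are removed row-wise from both blocks.

## Block construction

B1 columns: gaze proportion + one range per configured AU.  The default
AU set is the 12 OpenFace regression AUs covering every muscle named in
the latent-structure interpretations (AU01, AU02, AU04, AU06, AU09,
AU10, AU12, AU14, AU15, AU17, AU20, AU25), for 13 instrumental
variables in total.  **This set is a reconstruction**: the original
variable table is not available in transcribed form, so the set is
configurable and should not be treated as canonical.

B2 columns: one-hot indicators for subject (18), gender (2), stimulus
type (3) and trial position (3) — 26 columns.  This 18 + 2 + 3 + 3
decomposition is likewise a documented reconstruction: it is the unique
natural coding that reproduces the published column count and contains
every feature the interpretation uses.  Redundant groups (both genders,
all three conditions) are kept rather than reduced to reference coding:
2B-PLS tolerates exact collinearity, and full groups keep every level
visible in the loadings.  Binary columns are centered and scaled like
any other column; bringing the low-variance indicator block and the
higher-variance instrumental block to comparable scale is the point of
scaling both.

Trials, not subjects, are the model's objects — otherwise trial-order
indicators could not vary within the block.  The full design yields
18 × 3 × 3 = 162 rows.

## The synthetic cohort generator

What it emulates: the study design (18 subjects, 8 men / 10 women;
blank screen always first, own-/other-face order counterbalanced;
3 × 2-minute eyes-open trials per condition at 30 fps) and the
frame-level texture of tracker output (AR(1) noise with lag-1
correlation 0.9 — white noise would make ranges grow degenerately with
trial length — occasional low-confidence frames and tracking failures).

AU traces are baseline + subject offset + AR(1) noise + expression
events: 0.5–2 s Hann bumps at ≈0.05 events/s (≥1 per trial), whose
amplitude carries the planted effects, because the analysis statistic
is the range and ranges are driven by excursions.

Planted defaults (AU intensity units on event amplitude, hence ≈ on the
range):

| effect | variables | default |
|---|---|---|
| gender × first trial (F +, M −) | AU14, AU20 | ±1.0 |
| … broad component (same sign) | all other AUs | ±0.3 |
| gender × first trial on gaze (M +, F −) | dwell prob. | ±0.18 |
| own face + / blank − | AU06 | ±0.35 |
| own face + / blank − on gaze | dwell prob. | ±0.10 |
| third trial | AU17 +0.25, AU04 +0.25, AU01 −0.25, AU25 +0.25 | |
| subject effects | baseline sd 0.10, amplitude sd 0.15 | |

The gender × first-trial effect has a broad secondary component so that
the leading latent structure is a *general* axis rather than a
two-variable one.  Magnitudes were calibrated once so that the first
structure's variance share falls in the 40–60 % band at the default
design (measured 0.50–0.57 over seeds; this echoes, and must not be
read as reproducing, the published ≈54 % figure — the published value
comes from real human data this generator does not model).

Gaze is simulated as 1 s dwell segments, each on-screen with a
condition/gender/trial-dependent probability (base 0.65); on-screen
frames get N(0, 0.05 rad) angles per axis, off-screen frames magnitude
≈0.35 rad, so the 10° threshold separates the states essentially
perfectly and the measured proportion estimates the dwell probability.

What it does **not** model — and hence what passing tests do not show
about real data: facial appearance (the tracker itself is out of
scope), correlated AU co-activation patterns, non-stationary drift,
blink/eyes-closed segments, real gaze dynamics (smooth pursuit,
saccade statistics), and realistic dependence of tracker confidence on
expression.  Recovery results certify the *pipeline and estimator*,
not the biology.

`generate_blocks` is the block-level shortcut: a rank-1 shared latent
score propagated into both blocks at signal-to-noise ratio `snr`
(per-element signal sd / noise sd), plus unit Gaussian noise.  Default
`snr = 2.0`: the planted cross-covariance singular value
(≈ snr²·n = 648 at n = 162) then exceeds the expected noise operator
norm (≈ √n(√p1 + √p2) ≈ 110) by a comfortable but not degenerate
margin.  Weight recovery at that default exceeds |r| > 0.9 in
effectively all replicates; in the noiseless limit recovery of the
planted pattern is exact under center-only preprocessing (unit scaling
intentionally discards planted weight magnitudes, which is why the
noiseless check uses `mode="center"`).

## Numerical choices

* Orthonormality/conservation asserted at 1e-10; score cross-covariance
  diagonality at 1e-8 in absolute terms (singular values reach
  hundreds, so this is ≈1e-12 relative).
* Brute-force oracle (tests): the first singular value is compared with
  a dense grid maximisation of cov(Z1u, Z2v) over the unit sphere of
  the smaller block (for fixed u the optimal v is closed-form);
  300 000 grid points bound the grid error well below the 1e-3
  comparison tolerance.
* Zero-variance columns: flagged, centered to exactly zero, never
  fatal; `variance_shares` raises only when *all* singular values are
  zero.
* Constancy detection uses a relative round-off tolerance
  (sd ≤ 1e-12 · max(1, max|x|)) rather than exact zero.
* AU intensities are clamped to [0, 5] on read rather than rejected:
  regression outputs legitimately overshoot the scale slightly.
* Seeds: one `numpy.random.default_rng(seed)` drives a cohort, drawing
  subject effects then trials in a fixed order, so a seed fully
  determines every file written (floats formatted at fixed precision).

## Problem sizes used in the checks

The automated checks run the full 18-subject design at full trial
length where the quantity depends on it (direction recovery, the
acceptance script's structural count at 120 s × 30 fps), and shortened
trials (5–6 s) where only the design shape matters (structure counts,
alignment, determinism), since the block dimensions — and hence K — are
independent of trial length.  Monte-Carlo checks use 20–100 seeded
replicates with permutation nulls of 199–499 draws.

## Known limitations

* The 13-variable and 26-variable block compositions are reconstructions
  (see above); both are configurable.
* Loading significance via the t-test ignores the repeated-measures
  structure of trials within subjects.
* No automated scree-elbow detection and no component-number selection:
  the scree table is exported for visual reading, which is how the
  quantity is used in practice.
* The CLI's `--null` cohort still contains design-balanced indicator
  structure in B2; "no planted effects" means B1 carries no signal
  about B2, not that B2 is random.
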