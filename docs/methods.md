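# Methods

This note documents the models, parameters and numerical choices behind
`adaptune`, and what the bundled synthetic data can and cannot establish.

## Similarity substrate

Object similarity is the cosine between raw feature-production-frequency
vectors (counts of norming participants listing each feature for each
object), unweighted — no tf-idf or feature-type weighting.  Cosine is
scale-invariant per object, so production-frequency magnitude differences
between objects do not leak into similarity.  Deviant bins are half-open
similarity intervals, closed on the low side, so a similarity exactly on a
cut point falls in the lower bin; the default cut points are the
quartiles of the off-diagonal similarity distribution.  Numeric cut
points for the original four bins were never published, so the quartile
default is a documented choice, not a recovery of the originals; the
bins are a configuration parameter for users with their own norms.

The bundled synthetic norms (`synthetic_feature_norms`) plant a family /
group / global feature hierarchy purely so that every family head has
candidate deviants in all four quartile bins.  They emulate the
*structure* needed by the binning stage, not the content statistics of
elicited norms (feature-type proportions, production-frequency
distributions).

## Designs

Behavioral: 10 adaptors × 5 adaptation lengths (5–9) × 5 deviant
conditions × 2 repetitions = 500 trials; every deviant condition occurs
100 times; deviants shown 3× per trial.  fMRI: 50 trials per run — every
adaptor–deviant pair exactly once, each condition and each length 10
times — deviants shown 2×, 16 s fixation at both ends, 500 ms stimulus +
500 ms blank so events sit on the 1 s TR grid.  "Pseudo-random" order is
realized as a seeded shuffle with one constraint: the same adaptor object
never occupies consecutive trials (sequential sampling with restart; the
constraint is vacuous when only one adaptor exists).  Whether the
original order also balanced condition transitions is unknown; only this
constraint is implemented.

## BOLD generator

Per voxel, the k-th adaptor drives neural amplitude
`A · max(floor, decay^(k−1))` and a deviant drives `A · w(condition)`;
the impulse train is convolved with a double-gamma HRF (response gamma
shape 5 → mode at 4 s, undershoot shape 16 scaled by 1/6, 32 s support,
unit peak).  Defaults `decay = 0.5`, `floor = 0.1` were chosen once so
that the peristimulus BOLD trajectory reproduces the documented
adaptation phenomenon — a rise to a peak about 4–5 s after trial onset
and a decline toward a plateau before 10 s — which is what makes the
4th > 7th time-bin contrast sensitive.  Release archetypes:
graded-linear `w = (0.4, 0.6, 0.8, 1.0)` over SC..SD and step-like
`w = (0.4, 0.85, 0.85, 0.85)`; identity weight 0.3 in both, below every
deviant weight.  The default grid is 12×12×8 voxels with a graded block
(75 voxels), a step block (48) and a silent remainder.

Noise: AR(1) (φ = 0.3, marginal sd 0.25 in signal units), a linear drift
whose per-voxel coefficient is drawn fresh each run (zero-mean across
subjects, so group contrasts stay unbiased even though the GLM carries no
drift regressor), and 24 simulated nuisance regressors — 6 random-walk
motion traces and 18 quasi-periodic cardiac (6) / respiratory (8) /
interaction (4) sinusoids with frequency jitter — that load linearly on
each voxel and are returned for use as GLM confounds.  Not emulated:
anatomy, spatial autocorrelation, motion as spatial displacement,
susceptibility artifacts, and physiological noise derived from real
pulse/respiration traces.  Passing tests therefore certify the
statistical machinery under a correctly specified (if simplified) signal
model, not robustness to preprocessing failures in real data.

RT generator: `rt = base + slope·level + subject intercept + trial
noise`, levels (3, C*, D*, 0) for (SC, C, D, SD) where the optional
plateau sets C* = D* (default 0.8 bins above SD), emulating the typical
pattern of a strong SC cost with near-equal intermediate bins.  Defaults:
base 416.7 ms, slope 10.6 ms/bin, subject sd 30 ms, trial sd 100 ms,
miss probability 8.5 % plus 3 points for SC.  Misses are Bernoulli, plus
any response falling outside the validity window.

## GLMs and the adaptation contrast

The FIR design has one *stick* regressor per adaptor position and per
deviant condition (14 when all occur; positions or conditions absent from
a degenerate run are dropped rather than carried as all-zero columns),
plus nuisance and intercept.  Because every stimulus-stream volume
carries exactly one stick, stick betas estimate the peristimulus BOLD
time course.  `convolve_hrf=True` instead convolves the position
regressors with the canonical HRF, turning the model into a per-position
*amplitude* estimator: on noise-free simulated data it returns the
planted amplitudes exactly, and under the responsive non-adapting null it
is exactly calibrated.  The stick estimator carries a small deterministic
bias in position contrasts from the run-boundary hemodynamic ramp (the
first trial's early positions sit on the rising transient); its
calibration is therefore certified on the non-responsive null, and the
bias is a known limitation of stick-FIR position contrasts in general.

Fitting is plain OLS via thin QR (no prewhitening; the group inference is
a random-effects t across subjects, which is exact under the null as long
as subject-level contrasts are independent across subjects, regardless of
within-run autocorrelation).  The "repeated-measures F" on the single-df
4th−7th contrast is implemented as the squared one-sample t (algebraically
identical for one contrast); the adaptation mask additionally requires a
positive mean difference, as the hypothesis is directional.  The
deviants-vs-identity map is produced as a sanity output only and never
feeds the analysis mask.

## Release inference

Within the adaptation mask each voxel's four deviant betas are regressed
on similarity rank 1..4 (equally spaced; measured cosine similarities can
be substituted via `similarity_x`).  `slope = cov(x, β)/var(x)`;
`R² = 1 − SSE/SST`, defined as 0 for a flat voxel.  Group inference:
one-sample t across subjects, TFCE with the FSL-randomise conventions
(H = 2, E = 0.5, 26-connectivity, dh = max/100; all configurable), and a
sign-flip max-TFCE null.  The unflipped arrangement is counted once via
the (1 + x)/(1 + N) p-value and excluded from the random draws —
re-drawing it would tie with the observed statistic and double-count the
identity, which matters at the 1/(1+N) resolution.  R² maps are
non-negative, so the sign-flip null on R² is not sign-symmetric; testing the R² map is the
paradigm's conventional choice, while `stat: slope` offers the
sign-symmetric alternative used for the calibration studies.  The final
release mask intersects significance with a positive group-mean slope.

## Clustering

Voxel tuning curves (group-mean deviant betas per fold, z-scored per
voxel across the four conditions; Identity excluded) are clustered with
k-means (squared Euclidean, 20 restarts, fixed seed), with k chosen by
the Calinski–Harabasz index; a best-to-runner-up CH ratio below 1.2 is
flagged as low confidence.  Leave-one-subject-out folds re-cluster the
remaining subjects' means; labels are aligned across folds by Hungarian
matching of centroids, with cluster 1 defined as the steepest (largest
SC→SD slope) archetype.  Held-out curves come only from the fold that
excluded that subject.  Consensus masks keep voxels assigned to a cluster
in strictly more than 75 % of folds (16 of 20), capped at all folds so a
threshold of 1.0 is the intersection.  Cluster comparison z-scores each
subject's concatenated cluster × condition curves, compares SC→SD slopes
with a paired one-tailed t (cluster 1 steeper) and a Wilcoxon signed-rank
test, runs the six pairwise deviant contrasts per cluster two-tailed with
Bonferroni (m = 6), and excludes subjects whose grand-mean beta exceeds
the group mean by more than 3 SD (upper tail only, matching the
phenomenon of runaway beta magnitudes).

## Behavioral statistics

Validity window 100–800 ms with *inclusive* bounds ("between 100 and
800 ms as valid"); a trial is a miss iff unanswered or outside the
window.  The within-subject one-way ANOVA uses the classical
decomposition — `F = MS_cond / MS_cond×subj`, df `(k−1, (k−1)(n−1))`,
partial η² = SS_cond/(SS_cond+SS_err) — with no sphericity correction by
default (uncorrected dfs are the convention in this paradigm).  Bonferroni
family size defaults to the six pairwise tests and is raised (with a
logged warning) if set smaller.

## Problem sizes

Defaults throughout the tests and demo are deliberately desk-scale: a
12×12×8 voxel grid, 12–20 simulated subjects, one 50-trial run per
subject (25-trial runs for the calibration studies), 500–1000
permutations at FWE α = 0.001–0.05, and 100–200 Monte-Carlo replicates
for calibration.  These sizes make the whole pipeline run in seconds to a
few minutes while leaving every statistical claim testable; all are
configuration fields for larger studies.

## Known limitations

* The generator's voxels are spatially independent; TFCE's benefit under
  realistic smoothness is not exercised.
* Stick-FIR position contrasts inherit the run-boundary transient bias
  described above; with the default fast-decay phenomenon the planted
  effect dwarfs it, but near-null decay values would not be detected as
  cleanly as the amplitude-estimator route detects them.
* The pipeline consumes preprocessed-equivalent volumes; registration,
  smoothing, slice timing and ICA-based denoising are out of scope.
* Identity-condition data are carried descriptively only and never enter
  the similarity regression or clustering features.
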