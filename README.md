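# adaptune

Release-from-adaptation fMRI analysis for object-similarity tuning curves,
with a bundled synthetic-data generator so every stage is testable without
any imaging download.

## The problem

When the brain sees the same kind of object over and over (five to nine
exemplars of, say, scissors), the BOLD response in object-selective cortex
adapts.  When a *deviant* object interrupts the sequence, the response
recovers — and the size of that recovery indexes how differently the
deviant is represented from the adapted object.  By grading the
adaptor–deviant similarity into four bins — super-close (SC), close (C),
distant (D), super-distant (SD), plus an identity (I) control — the
release from adaptation traces a *similarity tuning curve*, behaviorally
(reaction times to detect the change) and neurally (per-condition GLM
betas).  `adaptune` implements the full analysis chain for this paradigm:

1. **Similarity norms** — between-object similarity is the cosine between
   feature-production-frequency vectors,
   `s(i,j) = ⟨f_i, f_j⟩ / (‖f_i‖‖f_j‖)`, and deviants are binned per
   adaptor into SC/C/D/SD with strict ordering `s(SC) > s(C) > s(D) > s(SD)`.
2. **Experiment design** — behavioral blocks (500 trials; 10 adaptors × 5
   adaptation lengths × 5 deviant conditions × 2) and fMRI runs (50
   trials, 10 per deviant condition and per length, 16 s lead/trail
   fixation, 500 ms stimulus + 500 ms blank on a 1 s TR grid).
3. **Behavioral statistics** — 100–800 ms validity window (bounds valid),
   miss percentages, within-subject one-way ANOVA
   (`F = MS_cond / MS_cond×subj`, df `(3, 3(n−1))`, partial η²) and
   Bonferroni planned comparisons.
4. **Adaptation GLM** — FIR model with 14 stick regressors (adaptor
   positions 1–9 and the five deviant conditions) plus 24 nuisance
   regressors (6 motion, 18 physiological) and an intercept; voxel-wise
   OLS via QR; the adaptation mask is the repeated-measures F on the
   4th−7th time-bin difference at p < 0.001 with a positive mean.
5. **Release inference** — a six-regressor HRF GLM (all adaptors + SC, C,
   D, SD, I); inside the adaptation mask each voxel's four deviant betas
   are regressed on similarity rank, giving per-subject R² and slope maps;
   group inference is a sign-flip one-sample permutation test with
   threshold-free cluster enhancement
   (`TFCE(v) = Σ_h e(h,v)^E · h^H · dh`, H = 2, E = 0.5, 26-connectivity)
   and max-statistic FWE control; significant voxels with a positive
   group-mean slope form the release mask.
6. **Tuning clusters** — Calinski–Harabasz selection of k, k-means on
   per-voxel z-scored tuning curves, leave-one-subject-out ROIs with
   centroid-matched labels, 75 % consensus masks, and cluster comparisons
   (paired one-tailed t and Wilcoxon on SC→SD slopes, Bonferroni pairwise
   deviant tests, > 3 SD outlier exclusion).

The synthetic generator plants all of this: RTs that slow with similarity,
and voxels whose neural amplitude decays multiplicatively across the
adaptation sequence (`a_k = A·max(floor, decay^(k−1))`) and recovers on
deviants by `A·w(condition)`, with a graded-linear and a step-like tuning
archetype, convolved with a double-gamma HRF and contaminated with drift,
AR(1) noise, and motion/physiological nuisance signals.

It is written for cognitive-neuroscience researchers who want to run,
audit, or extend this analysis on BIDS-style events, NIfTI volumes, and
feature-norm CSVs.

## Worked example

```python
from adaptune import demo_config, run_pipeline

cfg = demo_config(out_dir="demo_out", seed=1, n_subjects=12)
results = run_pipeline(cfg)
print(results["report"])
```

With seed 1 this prints (abridged):

```
adaptation_mask_voxels : 123        # the 123 planted tuned voxels, exactly
release_mask_voxels    : 123
k_selected             : 2
cluster_comparison     : slope_means [0.94, 0.63], slope_t 60.8,
                         slope_p_one_tailed 1.5e-15, wilcoxon_p 2.4e-4
behavior               : RT means SC 449.3, C 423.1, D 428.6, SD 419.5 ms
                         ANOVA F(3,33) = 19.69, p < 1e-7, partial eta^2 = 0.64
```

Reading: the 4th>7th FIR-bin contrast recovers every planted
adaptation voxel; TFCE permutation inference keeps all of them as
similarity-tuned; Calinski–Harabasz picks two tuning-curve clusters whose
archetypes (graded-linear vs step-like) are separated with cluster 1
significantly steeper; and simulated RTs reproduce the behavioral
signature (slowest for SC, ANOVA on condition means highly significant).

The same stages are scriptable from the shell:

```bash
adaptune design --mode fmri --seed 0 --out events.tsv
adaptune run --config examples/demo.yaml --out demo_out
```

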