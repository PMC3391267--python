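# Methods

## The analysis model

The pipeline measures whether a region's multi-voxel activation pattern is
read out for behavior. Per subject:

1. **Trial-wise estimation.** Each run's voxel time courses are fit by
   ordinary least squares with one boxcar regressor per trial
   (least-squares-all), polynomial drift and a constant. The compound trial
   (two face images shown in sequence) is modeled as a single boxcar from
   first-image onset (0.7 s after trial start) to second-image offset
   (2.2 s), i.e. a 1.5-s window spanning exactly the stimulation period; the
   window is config-exposed (`analysis.stim_window`) since nothing forces
   this choice. Boxcars are convolved with the gamma HRF
   h(t) = ((t−δ)/τ)^α e^−(t−δ)/τ (δ = 2.25 s, τ = 1.25 s, α = 2,
   peak-normalized, FS-FAST parameterization; peak at δ + ατ = 4.75 s) on a
   0.1-s oversampled grid and sampled at scan midpoints (k + ½)·TR. A
   least-squares-separate estimator is available behind
   `analysis.beta_method = "lss"`.
2. **ROI definition.** A blocked localizer is fit condition-wise; the
   faces-minus-objects t-map is thresholded one-tailed at p < 0.01
   (uncorrected; the contrast is directional), connected components are
   labeled under 26-neighborhood connectivity (both config-exposed), and the
   component containing — or nearest to — the expected anatomical seed
   voxel is kept if it reaches `roi_min_size`. No surviving component is an
   explicit exclusion signal, mirroring cohorts in which a region cannot be
   localized in every subject; excluded subjects drop out of the affected
   contrasts listwise, and dfs are reported, never assumed.
3. **Split-half reliability.** Trials without a behavioral response are
   excluded (they are < 0.1 % by default). Runs with odd 1-based index form
   the "odd" half. Per half, amplitudes are averaged in each condition ×
   response cell; each voxel's mean over the four cell patterns of that half
   is subtracted (cocktail-blank centering, which removes any voxel-wise
   offset shared by the cells); the Pearson correlation between a cell's odd
   and even centered mean pattern is its reliability. Fisher-z transformed
   correlations are available (`analysis.fisher_z`) but off by default, and
   undefined correlations (empty cell, zero variance) propagate as missing
   values rather than zeros.
4. **Group inference.** Every effect of interest is a 1-df within-subject
   contrast: per subject the four (or eight, for two-region analyses) cell
   values are combined with weights normalized to a difference of means, and
   F is the squared one-sample t of those scores, df = (1, n−1),
   partial η² = F/(F + df2). This is algebraically the corresponding
   repeated-measures ANOVA effect, verified in the tests against a full
   sums-of-squares decomposition and an independent library implementation.
   Cohen's d for paired comparisons is mean(diff)/sd(diff). All tests are
   two-tailed, uncorrected, α = 0.05 (configurable).
5. **Verdict.** A significant interaction with a correct > incorrect
   post-hoc for veridical faces only is labeled "holistic"; with both
   post-hocs significant, "both"; no interaction but a positive response
   main effect, "parts_based"; otherwise "null". A significant interaction
   without the post-hoc pattern returns "indeterminate" rather than forcing
   a label.

Two controls accompany the primary analysis: **trial-count matching**
(within each response type and half, the condition with more trials is
randomly subsampled, once per seed, to the other's count) and the **pooled
mean magnitude** per cell, the traditional univariate analysis.

## The synthetic cohort generator

The generator emulates a whole-part discrimination session: per run, 36
veridical and 36 scrambled 4-s trials plus twelve 2-s fixation jitters
between 8-s lead-in/lead-out (328 s at TR = 2 s, 164 scans); ten runs per
subject; a 336-s blocked localizer (sixteen 16-s blocks, four categories
appearing once per quarter, five interleaved 16-s fixations, 20 stimuli of
300 ms on / 500 ms off per block). Trial order is a seeded permutation with
a first-order transition-count diagnostic in place of a counterbalancing
optimizer — optimal jitter efficiency matters for real SNR budgets, not for
the validity checks this generator serves.

Behavioral correctness is Bernoulli per condition (defaults 0.847 veridical,
0.727 scrambled; no-response rate 0.001). Reaction times are a shifted
lognormal, RT = 0.3 s + exp(N(log m, 0.35²)) with m = 0.55 s veridical and
0.75 s scrambled; only the ordering veridical < scrambled is anchored — the
scale is a free choice at plausible values, since accuracy, not RT, carries
the calibration targets.

Neural ground truth lives on a 20 × 20 × 10 grid of 3 × 3 × 4 mm voxels with
two compact regions, `ffa_like` (28 voxels) and `ofa_like` (32 voxels),
sized after typical right-hemisphere localizer counts and built as the N
grid points nearest an ellipsoidal center in millimeter metric. The trial
amplitude of voxel v in cell c and data half h is

    a[v,t] = μ_cond + s_c · p[v,c]
             + (1 − s_c) · ( √(1−w) · η[v,c,h] + √w · ε[v,t] )

with p a fixed per-subject cell pattern, η a cell-by-half state fluctuation,
ε i.i.d. per-trial noise (all unit-variance × `pattern_sd`), s_c ∈ [0,1] the
cell's **stability** and w the per-trial share of the unstable variance.
Across-half reliability of the cell-mean pattern is 1 at s = 1 and falls to
0 as s → 0. The scenario sets the stability table: `holistic` raises only
veridical-correct, `parts_based` raises both correct cells, `both` raises
veridical-correct fully and scrambled-correct by half, `null` leaves all
cells equal. Condition means are μ = 1.0 (veridical) and 0.93 (scrambled),
so the pooled magnitude carries a small condition scaling but no
correct/incorrect structure — which is exactly why the magnitude control
shows nothing where the pattern analysis does.

**Why the half-level noise component.** If the unstable variance were purely
per-trial, the noise in a cell's mean pattern would shrink as 1/n with the
cell's trial count, making expected reliability an artifact of how many
trials land in a cell. With realistic accuracies the four cells have very
unequal counts (incorrect veridical trials are the rarest), so a pure
per-trial mechanism would manufacture correct > incorrect "effects" under a
null ground truth at any noise scale — the bias is scale-invariant relative
to the sampling spread of r. The η term models slow state fluctuations
(attention, arousal, scanner state drifting between runs) whose effect on
reliability does not average out with trial count; with the default
`trial_noise_fraction = 0.2` the residual count dependence is far below the
sampling noise of r (verified by the null calibration study), while trial-
level variability remains present for the GLM to contend with. Trials
without a response receive μ_cond plus unit noise and no stable pattern;
they are filtered before analysis.

The BOLD forward model pushes these amplitudes through the same
boxcar-convolved HRF used in estimation, over a baseline of 100, plus a
random linear drift per voxel (sd `drift_amp` = 1.0 over the run) and AR(1)
noise (marginal sd `sigma_thermal` = 0.5, φ = 0.3, stationary start). With
noise set to zero the trial GLM inverts this model exactly (recovery to
1e−6 is an acceptance check), which also licenses the **amplitude-level
shortcut** used by the large calibration studies: `simulate_session_estimates`
returns the generative a[v,t] directly, skipping the forward model and GLM
whose estimation noise is symmetric across cells and therefore cannot
change null calibration.

### Default effect size and calibration

`stability_base = 0.4`, `stability_effect = 0.25` were tuned, as the
config's documented defaults, so that the default 13-subject, 10-run cohort
meets a design power target of at least 0.8 for the interaction under the
holistic scenario (measured ≈ 0.95, with the full verdict pattern ≈ 0.9,
via 50-cohort recovery studies), while 2000 null cohorts at reduced volume
(single 28-voxel ROI, 4 runs) keep every 1-df test's rejection rate inside
the 99 % binomial interval around 0.05. These study sizes — 2000 cohorts
for calibration, 50 for recovery — are the package's validation scales,
chosen to make the binomial intervals decisive at desk scale.

## Numerical choices

- OLS via explicit normal equations with inversion; rank deficiency falls
  back to a pseudo-inverse with a warning, and dof = scans − rank.
- Trial regressor pairs with |r| > 0.99 abort estimation (unestimable).
- Drift columns are Legendre polynomials on [−1, 1]; drift order 1 by
  default for trial GLMs.
- Gaussian smoothing uses σ = FWHM / (2√(2 ln 2)) per axis in voxel units;
  FWHM 0 is the identity. The synthetic pipeline defaults to no smoothing:
  on piecewise-constant ground truth, smoothing raises boundary-shell
  voxels' t to interior levels (signal and noise attenuate together), so it
  only blurs the ROI boundary; on real data a 5-mm kernel for the localizer
  stream is the conventional choice and is config-exposed.
- Seeds: one master seed; every stochastic step derives a 31-bit child seed
  by SHA-256 hashing of (master, purpose tags), so streams are stable under
  reordering of stages.
- Degenerate statistics: sd(diff) = 0 yields t = 0, d = 0, p = 1 when the
  mean difference is also 0, and NaN otherwise; both carry an explicit
  `degenerate` flag.
- Ties in ROI component selection resolve to the component nearest the
  anatomical seed (Euclidean in voxel indices).

## What passing tests do and do not show

The generator contains no head motion, physiological noise, multi-band
artifacts, spatial autocorrelation beyond the ROI structure, anatomical
variability, or between-subject variation in stability; hemodynamics are
identical across voxels and subjects and match the analysis HRF exactly.
Passing the recovery and calibration suites therefore demonstrates that the
*estimators and statistics* are correct and calibrated under their own
assumptions — not that the pipeline is robust to the mis-specification real
fMRI brings. Two substantive caveats carry over to real data: with unequal
trial counts the split-half correlation estimator retains a small
count-driven bias through per-trial (including GLM estimation) noise, which
is the reason the matched-trial control exists and should accompany any
real-data claim; and the least-squares-all single-trial estimator is known
to be noisy at short inter-trial intervals, which the generator's 4-s
spacing inherits.
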