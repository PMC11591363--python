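# Methods

## The analysis problem

The package quantifies locomotor deficits in rodent tunnel-walk
recordings.  Joint positions (metatarsus, ankle, knee of both hindlimbs)
are annotated frame by frame in 240 fps video; the analysis must make
step curves comparable across animals, steps and days, and then decide
(i) how different a lesioned group's gait is from control overall, and
(ii) where in the step cycle the difference lies.

The processing chain is:

1. **Projective correction.**  The walking surface is planar, so the
   map from image pixels to arena coordinates is a 3×3 homography fixed
   by four point correspondences.  Estimation uses the direct linear
   transform on exactly four points with Hartley normalization
   (centroid 0, RMS radius √2 in both frames) for conditioning; the
   estimate must reproduce every calibration pair to a relative 1e-8.
   A homography cannot represent radial lens distortion; only the
   projective component is corrected, and the destination frame is
   arena centimeters with y up, so the same matrix performs the video
   axis flip.

2. **Step-cycle normalization.**  Each annotated step (its start/end
   frames are inputs) is cut from the track, re-timed from step onset,
   and by default re-zeroed so its first sample is (0, 0) — curves then
   encode within-step displacement rather than arbitrary tunnel
   position, without which the dissimilarity statistic would be
   dominated by where in the tunnel the step happened.  An
   interpolating cubic spline (not-a-knot) is fitted to x(t) and y(t)
   and evaluated at 100 equally spaced times spanning the step,
   endpoints included, giving bin *i* at 100·(i−1)/99 percent of the
   cycle.  Interpolation is in time, not path length.  Annotation gaps
   of ≤ 3 consecutive frames (12.5 ms at 240 fps) are bridged linearly;
   longer gaps invalidate the step, which is logged and excluded.
   Because the spline interpolates rather than smooths, linear curves
   are reproduced exactly and normalization is idempotent and invariant
   to uniform time stretching.

3. **Dissimilarity factor.**  For two normalized curves *a*, *b*,

   DF(a, b) = (1/200) [ Σᵢ (x_a(i) − x_b(i))² + Σᵢ (y_a(i) − y_b(i))² ],

   the mean squared per-bin difference pooled over the horizontal and
   vertical components.  No square root is applied; the
   root-mean-square variant is available as `metric="rmsd"`.  Pairing
   follows a fixed scheme within each (side, joint, day) stratum: every
   experimental step curve against every control step curve
   (`cross_group`), and for the control group's own reference
   distribution every pair of control curves from two *different*
   animals (`control_baseline`).  Percent differences between group
   means are reported as 100·(mean_exp − mean_ref)/mean_exp, i.e. how
   far the reference mean falls below the experimental mean; the
   denominator is configurable because the convention is not uniquely
   fixed by how such percentages are usually quoted.

4. **Per-bin significance maps.**  One-dimensional statistical
   parametric mapping in its simplest form: an independent two-sample
   pooled-variance t-test at each of the 100 bins of the vertical (VD)
   and horizontal (HD) components, flagged at p ≤ α (default 0.05),
   with *no* correction across bins by default — the flagged-bin count
   out of 100 is exactly the "% of the step cycle differing" reporting
   unit.  Bonferroni or Benjamini–Hochberg correction across bins and
   Welch's t are available but off by default.  Bins where both groups
   are constant and equal give t = 0, p = 1.

5. **Group statistics.**  One-way ANOVA with post hoc two-sample
   t-tests under Bonferroni correction (family = the pairwise
   comparisons actually run), or Kruskal–Wallis with Dunn's rank
   z-tests (tie-corrected) as the nonparametric alternative.  Stars at
   adjusted p ≤ 0.05/0.01/0.001/0.0001.

## Statistical unit

The default output treats every DF pair value as one observation,
matching how such distributions are usually plotted.  Pair values
sharing a curve are not independent; the package therefore also exposes
animal-level aggregation (`animal_mean_df`: mean DF per experimental
animal).  In null simulations the pair-level ANOVA rejects a true null
far above nominal (≈ 0.75 at α = 0.05 in our measurements) while the
animal-level test is calibrated — users drawing inferential conclusions
should use the animal level.  The calibration experiments in
`gaitdf.validation` additionally measure every group, the control study
group included, against a *held-out* control reference cohort with the
same cross-group scheme: mixing the baseline pairing scheme into the
same ANOVA is measurably anti-conservative (≈ 0.086 over 800 null
replicates) because baseline and cross-group values respond differently
to noise in the shared control curves, whereas the exchangeable design
sits at the nominal level (≈ 0.05).

## Synthetic data generator

No recordings are distributed with the package, so validation runs on a
synthetic generator whose parameters are all recoverable by the
analysis.  The per-step template is

* x(phase) = stride_length · s(phase), s piecewise linear and monotone,
  slower during stance (fraction `duty_factor` = 0.6 of the cycle,
  stance slope = 0.4 × swing slope) — the paw advances little while
  loaded and quickly during swing;
* y(phase) = swing_peak_height · raised-cosine bump centered at
  `swing_peak_phase` = 0.75 with width 1 − duty_factor, zero on the
  ground.

Defaults are order-of-magnitude choices at rat scale, documented as
such: step duration 0.2 s, stride 8 cm, swing peaks 1.5/1.0/0.6 cm for
metatarsus/ankle/knee, per-sample noise σ = 0.08 cm.  Injury is
expressed as swing-peak attenuation, a circular phase delay of the
bump, an additive offset over a window of cycle bins, and extra noise;
effects can be lateralized, with a configurable fraction applied to the
contralateral limb (the default scenario uses 35%, mirroring deficits
that are weaker but not absent on the less-affected side).  Noise is
i.i.d. Gaussian per sample plus a per-animal Gaussian intercept
(σ = 0.1 cm) on stride length and peak height.  The intercept acts on
amplitudes rather than position because onset re-zeroing removes any
constant positional offset exactly — a positional "animal effect" would
be unobservable downstream by construction.

Randomness derives from one root seed through `SeedSequence` spawn keys
per (group, animal, day, side, joint, step), so identical configs
produce byte-identical datasets and any subset is independently
reproducible.

`default_paper_scenario` programs the qualitative injury/treatment
structure: strongest effects in the untreated ischemia group, weaker
with post-injury treatment, weakest with pre-treatment, none in sham,
left limb more affected, and slight worsening from 3 to 7 days.  Its
effect sizes (attenuations 0.45/0.52, 0.28/0.30, 0.18/0.19 for the
three lesioned groups at days 3/7, with phase delays and, for the
untreated group, a bin-41–60 offset) were calibrated by running the DF
pipeline until the group mean DF ordering
ischemia > ischemia+treatment > pre-treatment > max(sham, control) and
the left>right asymmetry held in ≥ 95% of seeded replicates; the
calibration simulations live in `gaitdf.validation` and the acceptance
script re-measures the rate.  The scenario makes no claim to reproduce
any particular numeric percentage, which would depend on the original
recordings.

`null_scenario` zeroes both the injury effects *and* the animal
intercept: with a nonzero intercept, curves within an animal are
correlated and curve-level tests cannot be expected to hold their
nominal level, so the calibration check would conflate test correctness
with pseudo-replication.

What the generator does **not** emulate: joint-angle coupling between
the three markers (each joint is simulated independently), stance-phase
ground-reaction detail, autocorrelated annotation error, step-duration
variability within a session, and day-to-day drift in healthy gait.
Passing tests therefore certify the pipeline's numerics and statistical
behavior under a known sampling model, not biological realism of any
particular effect size.

## Numerical choices and degenerate inputs

* Homography: collinearity rejected when any calibration triangle's
  area ≤ 1e-9 × bounding-box area; points mapping to |w| ≤ 1e-12 raise
  a projective-infinity error; matrices are normalized to H₃₃ = 1 and
  must have |det| > 1e-12.
* Spline: minimum 4 samples per step (cubic requirement); steps failing
  the gap rule or the minimum are excluded and counted, never silently
  dropped.
* Per-bin t-test: zero-variance equal-mean bins give p = 1; the
  significant fraction divides by the actual bin count so that with 100
  bins flagged bins equal percent directly.
* Serialization uses `repr` precision and a correctly rounded
  string-to-double parser, so write/read round trips are bit-exact and
  two runs with the same seed and config produce byte-identical tables.

## Problem sizes used in validation

Type-I calibration uses 500 replicates of 5 groups × 10 animals ×
2 steps; power/localization 50 replicates at 20 curves/group; ordering
recovery 100 replicates of the default scenario restricted to day 3 and
the metatarsus (the stratum the programmed effects target, with both
sides and all five groups at full size); the attenuation sweep uses the
default 10 animals × 5 steps.  These sizes give binomial standard
errors of about 1 percentage point on the estimated rates while keeping
a full validation run in the low minutes on one core.

## Known limitations

* The projective model cannot correct radial lens distortion; if the
  source video has noticeable barrel distortion the four-point
  correction leaves a residual that the DF statistic will absorb as
  apparent gait difference.
* DF conflates amplitude, phase and shape differences into one number;
  a phase shift and an amplitude loss of suitable sizes can produce the
  same DF.  The per-bin maps disambiguate but inherit the per-bin
  multiplicity issue (no across-bin correction by default, by design).
* Pair-level DF distributions overstate evidence; see "Statistical
  unit" above.
* The 13%-style pre-injury comparisons across pooled groups are not
  implemented as a dedicated operation; they can be assembled from
  `df_cross_group` outputs.
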