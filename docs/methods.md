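# Methods

This note documents the models, conventions and numerical choices behind
`kinesynergy`, and what the synthetic-data experiments do and do not show.

## Analysis pipeline

The pipeline quantifies how strongly the neuromuscular system drives each
whole-body *kinematic synergy* during steady treadmill walking, and relates
that to gait adaptability under belt-speed perturbations.

1. **Preprocessing** (`kinesynergy.io`). Marker trajectories (frames x
   markers x 3, meters; X mediolateral, Y anterior-posterior, Z vertical) are
   length-normalized to a fixed number of samples (default 5,000) by linear
   interpolation and low-pass filtered with a 4th-order Butterworth at 20 Hz.
   All filtering is zero-phase (forward-backward); phase distortion would
   corrupt the relative-phase measures downstream, so the effective order is
   doubled while the printed cutoffs are kept. Padding is ~10 filter time
   constants so polynomial trends pass without edge transients. Gaps up to 10
   frames are linearly interpolated; longer gaps are an error.

2. **Principal movements** (`kinesynergy.posture`). Each frame is a posture
   vector in R^(3M). Per trial, frames are re-referenced to the marker
   center of mass (unweighted mean per axis; a segment-mass-weighted variant
   would change constants, not structure), centered on the trial mean
   posture, and divided by the trial's mean Euclidean deviation norm so each
   trial contributes equal overall variance. Trials are pooled and
   eigendecomposed via SVD. The eigenvectors PM_k are the kinematic
   synergies; eigenvector signs are fixed by making the largest-magnitude
   loading positive. Scores PP_k are differentiated twice (central
   differences, one-sided at the ends) after a 3rd-order 10 Hz zero-phase
   filter, giving PV_k and PA_k. The control statistic is
   `PA_kRMS = sqrt(mean(PA_k(t)^2)) / speed`, the time-averaged RMS
   (duration-invariant) divided by belt speed in m/s.

3. **PM validation**. Leave-one-subject-out: PMs are recomputed without each
   subject and compared per vector as `arccos(|v_full . v_loo|)`; a PM is
   accepted when the maximum angle over left-out subjects is strictly below
   15 degrees. A Hann-windowed periodogram check verifies that score series
   carry at most 1% of their power above 5 Hz (movement data should be
   band-limited below that).

4. **Gait events** (`kinesynergy.events`). Heel strikes on the treadmill are
   the anterior peaks of the heel-minus-sacrum AP coordinate, with peak
   prominence at least 0.2x the signal IQR and a minimum separation of 0.4x
   the median cycle. Strides are the half-open intervals between consecutive
   same-side strikes, time-normalized to 100 points (0-100% gait cycle).

5. **Coordination variability** (`kinesynergy.coordination`). Sagittal joint
   angles: hip = thigh pitch from vertical, knee = thigh minus shank pitch,
   ankle = shank pitch minus foot incline; flexion positive. Phase angles
   come from the Hilbert analytic signal of the mean-centered angle
   (midrange centering available); CRP(t) = phi_proximal - phi_distal,
   wrapped to (-180, 180] with ties at +/-180 mapped to +180. The deviation
   phase DP of a joint pair is the *stride-to-stride* sample SD (ddof=1) of
   CRP at each percent of the cycle, averaged over the cycle; the trial DP
   averages the six sagittal pairs (hip-knee, hip-ankle, knee-ankle, both
   sides). The first and last 10% of the trial are excluded from stride
   assembly because the Hilbert transform distorts edges. The pointwise SD is
   a linear SD of wrapped values; it is accurate while CRP stays away from
   the +/-180 boundary, which holds for the lag conventions used here.

6. **Arm-swing smoothness** (`kinesynergy.smoothness`). Jerk is the third
   central-difference derivative of the (10 Hz low-passed) wrist trajectory;
   NJI = mean |jerk| / peak velocity magnitude (units 1/s^2), computed from
   the full 3-D trajectory norm (a vertical-only variant is a one-line
   change). Three samples are trimmed at each end after differentiation. NJI
   is invariant to amplitude scaling and rotation and scales as c^2 under
   time compression t -> t/c. The side with the higher NJI is carried into
   the statistics (ties go to the right side). Printed NJI magnitudes depend
   on the time-normalization convention; values here are seconds-based.

7. **Mixed-effects modeling** (`kinesynergy.models`). For each validated
   synergy k the maximal model is

       response ~ PA_kRMS + Trial + PA_kRMS:Trial
                  + (PA_kRMS | Participant) + (PA_kRMS | Trial)

   with response DP or DP x NJI and Trial the belt speed as an ordered
   factor. Backward elimination removes random terms first (REML
   likelihood-ratio tests, slope before the matching intercept), then fixed
   terms (Wald F-tests on the REML fit with a between-within denominator
   df `n - p - (g - 1)`; a small-sample stand-in for a Satterthwaite
   approximation whose null rejection rate we verified at 4-6% for alpha
   0.05). The fixed intercept is never removed. Candidate models are
   compared on ML-based AIC/BIC and chi-square LRTs for nested pairs;
   AIC = -2 logLik + 2 df and BIC = -2 logLik + df ln n hold by
   construction and are asserted in tests. Reported indices: ICC =
   sigma2_participant-intercept / (sigma2_participant-intercept +
   sigma2_residual) (the simple intercept form even when a slope is
   present), McFadden pseudo-R2 against a null with the same random
   structure and no fixed covariates (fixed-only) and against a
   fixed-intercept-only OLS null (total). Final fixed effects are gated at
   the Bonferroni level p < 0.007 (strict).

   Backend: statsmodels MixedLM. Participant-only structures use a
   correlated intercept+slope block; structures that also carry trial random
   terms are fit as independent variance components within a single group
   (crossed random effects without the intercept-slope correlation). During
   random-term elimination every candidate uses the independent-components
   parametrization so successive models stay nested; the reporting fit
   reverts to the correlated block. Every fit runs two optimizers (BFGS and
   Powell) and keeps the better likelihood — gradient-only optimization
   occasionally stalls at a spurious point on variance-component models.
   Boundary fits are flagged (`singular`, `converged`) rather than rejected;
   singular fits are excluded from model-selection winners unless all
   candidates are singular.

## The synthetic cohort

The generator (`kinesynergy.simulate`) emulates the study design the
pipeline targets: 13 subjects at 0.8/1.2/1.6 m/s, 100 Hz capture, ~50 s
steady walking and 8 min perturbed walking per speed, a 20-marker whole-body
layout (pelvis/sacrum, bilateral hip-knee-ankle-heel-toe, shoulders, elbows,
wrists, C7).

**Structured mode** builds marker motion from an exact sagittal
forward-kinematic chain driven by sinusoidal joint waveforms: hip 10 deg,
knee 12 deg (lag 45 deg), ankle 8 deg (lag 90 deg), arm counterswing 8 deg,
amplitudes scaling with sqrt(speed/1.2); stride frequency
0.9 x sqrt(speed/1.2) strides/s. A mediolateral torso sway (1 cm) rides at
the stride frequency and a vertical torso bounce (3 cm, the typical pelvis
excursion in walking) at its first harmonic, cos-phased with the stride so
it is coherent with the legs' kinematic first harmonic. The leg chain is
ground-referenced — stance-limb flexion absorbs the bounce — which keeps the
bounce a genuine shape change rather than a whole-body translation that COM
re-centering would remove. Joint-angle extraction from the generated markers
recovers the planted waveforms exactly (the chain is exact, not linearized).

*Planted DP.* In perturbed trials each joint waveform receives a
piecewise-constant per-stride phase offset, drawn independently per joint
with SD `phase_jitter_sd_deg / sqrt(2)`, so every joint-pair phase
difference has SD `phase_jitter_sd_deg` — the planted trial DP equals the
configured jitter (measured mapping is identity within ~1% across
2-20 deg). Steady trials are strictly periodic.

*Planted NJI.* A 7 Hz vertical wrist component (2 mm x `arm_jerk_scale`)
sits above the 5 Hz movement band and below the 10 Hz analysis cutoff, so
smoothness differences are attributable to it.

*Planted cohort model.* Each subject carries a standardized push-off control
score z (realized as a multiplier on the bounce harmonic) and random effects
(b0, b1); perturbed-trial jitter follows
`DP = baseline(speed) + (beta + b1) z + b0 + eps` clipped to 0.5-30 deg,
with baseline 12 + 3(speed - 1.2) deg. Defaults plant beta = -2.18,
intercept variance 3.08 and residual variance 3.84 (ICC 0.445). The default
random-slope SD is 0.3: a slope variance above ~1 would imply a
between-subject DP spread an order of magnitude larger than the DP SDs the
cohort is meant to exhibit, so the slope variance is kept small for internal
consistency. `simulate_model_dataset` draws the same structure directly as
a long table (PA values per speed ~ N(10.8/8.4/6.8, 1.3), matching the
normalized push-off PA_kRMS levels of the kinematic cohort) for
model-recovery experiments.

**Explicit-synergy mode** (pass `synergy_vectors`) generates posture
deviations exactly in the span of a supplied orthonormal basis with planted
variance fractions (leading component at the stride frequency, higher
components at successive harmonics in quadrature pairs, so scores are
mutually uncorrelated). `random_synergy_basis` produces COM-free bases
(zero net translation per axis) that are invariant under the COM
re-centering step.

**What the generator does not emulate:** soft-tissue artifact and marker
occlusion patterns, ground-reaction-force coupling, the actual belt-speed
perturbation waveforms (perturbations act as phase disturbances only),
transverse/frontal-plane kinematics beyond sway, and inter-subject
anthropometric variation. Passing recovery tests therefore shows the
*estimators* are correct and well-calibrated on data satisfying the model's
assumptions; it does not certify performance on noisy laboratory recordings.

## Recovery experiments (tests and `scripts/acceptance.py`)

Problem sizes are the package's own choices and are listed with each
benchmark: CRP plateau on 60 s of paired sinusoids; DP recovery over ~206
strides; synergy recovery on 6 subjects x 3 speeds x 20 s at a
total-signal-to-total-noise variance ratio of 100; leave-one-out validation
on 6-subject cohorts; mixed-model and stepwise behavior over 100 simulated
cohorts of 13 x 3; end-to-end determinism on a 5-subject pipeline run
executed twice.

Two constructions deserve notes:

- *Leave-one-out failure case.* A 45-degree rotation of one subject's
  PM2/PM3 plane alone cannot push the pooled eigenvector past 15 degrees:
  with mixing fraction p = 1/6 the rotation of the pooled eigenvector is
  bounded by tan(2 theta) = p/(1-p), about 5.7 degrees, and the per-trial
  variance normalization removes any overall variance boost. The failure
  scenario therefore gives the rotated subject in-plane fractions
  (0.50, 0.45, 0.05); under pooling, tan(2 theta) = 2 (f2 - f3) = 0.8, i.e.
  theta ~ 19 degrees, which the leave-one-out check correctly flags while
  PM1 stays stable.

- *Stepwise null behavior.* With five zero-effect terms tested at alpha =
  0.05 each, the probability that *all* are removed in one replicate is
  bounded near (1 - alpha)^5 even for perfectly calibrated tests, so the
  headline quantity is the pooled per-term elimination rate (measured
  ~0.97); per-term rates are reported alongside.

Known limitations: the intercept-variance ICC is upward-biased in small
cohorts when a random slope is estimated (the intercept sits ~9 PA units
outside the covariate range); REML variance estimates are nonnegative, so
their mean on zero-variance data is slightly positive — lme4 shows the
identical behavior (cross-checked numerically). The lme4 cross-check in the
test suite pins fixed effects, variance components and both likelihoods of
the random-intercept model to the reference implementation at 1e-3 relative
or better.

## File formats

Trials are stored as TSV: `#`-prefixed header lines (`fs`, `speed`,
`subject`, `condition`), then `<label>_X/_Y/_Z` column triplets in meters,
one row per frame, NaN for missing samples. C3D input is not supported in
this build; convert recordings to the TSV dialect first. Pipeline outputs
are CSV/JSON with a manifest carrying the full configuration and seed; a
fixed config + seed reproduces every output byte-for-byte.
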