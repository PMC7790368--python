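# kinesynergy

Movement-synergy analysis of gait adaptability: principal-movement
decomposition of whole-body motion-capture data, a speed-normalized
neuromuscular-control statistic (PA_kRMS), lower-limb coordination
variability (continuous relative phase and deviation phase), arm-swing
smoothness (normalized jerk index), and the linear mixed-effects workflow
that links them — exercised end-to-end on a synthetic gait generator with
known ground truth.

**Who it is for.** Movement scientists asking which whole-body kinematic
synergies of steady walking predict how well an individual copes with
perturbations, and methodologists who want a fully tested, simulation-backed
implementation of the PM / CRP-DP / NJI / mixed-model tool chain.

## The statistics at the core

- **Principal movements.** Pooled posture vectors (frames x 3M marker
  coordinates, COM-re-referenced, per-trial centered and variance-normalized)
  are eigendecomposed; the eigenvectors PM_k are kinematic synergies. Scores
  PP_k differentiate to accelerations PA_k, and

      PA_kRMS = RMS(PA_k(t)) / walking speed

  measures the magnitude of neuromuscular control on synergy k. PMs must
  survive leave-one-subject-out validation (eigenvector rotation < 15°).

- **Deviation phase (DP).** For each sagittal joint pair,
  CRP(t) = φ_proximal(t) − φ_distal(t) from Hilbert phase angles; DP is the
  stride-to-stride SD of CRP at each percent of the gait cycle, averaged
  over the cycle and over the six lower-limb pairs. Higher DP = more
  coordination variability.

- **Normalized jerk index (NJI).** Mean |d³r/dt³| of the wrist trajectory
  divided by peak velocity; lower = smoother arm swing. The noisier side is
  analyzed.

- **Mixed models.** Per synergy k:
  `DP ~ PA_kRMS + Trial + PA_kRMS:Trial + (PA_kRMS|Participant) + (PA_kRMS|Trial)`
  (and the same for DP x NJI), simplified by backward elimination (REML
  LRTs for random terms, small-sample Wald F-tests for fixed terms),
  compared across synergies by AIC/BIC/LRT, reported with ICC and McFadden
  pseudo-R², and gated at the Bonferroni level p < 0.007.

See `docs/methods.md` for conventions, numerical choices and the synthetic
cohort's design.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (13 subjects x 3 belt speeds, seeded):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_principal_movements.py
python analysis/03_adaptability_metrics.py
python analysis/04_mixed_models.py
```

`02` prints the synergy spectrum and its stability:

```
 pm  variance_fraction  loo_max_angle_deg  validated
  1           0.859208           0.005366       True
  2           0.095192           0.015934       True
  3           0.043917           0.193187       True
  4           0.000078          87.631498      False
```

PM1 is the dominant leg-swing pattern, PM2 the mediolateral sway, PM3 the
vertical push-off/bounce harmonic; PM4 is noise and fails validation. `03`
confirms the measured deviation phase tracks the planted stride-to-stride
variability (r = 0.975, median relative error 5.4%), and `04` shows the
model selection recovering the planted association:

```
planted DP-linked synergy: PM3 (alignment with the push-off pattern: 1.00)

DP: model comparison across synergies
            model  k  df    AIC    BIC  logLik  singular
DP ~ PA1_RMS_norm  1   6 182.00 191.98  -85.00     False
DP ~ PA2_RMS_norm  2   4 184.67 191.32  -88.33     False
DP ~ PA3_RMS_norm  3   3 178.10 183.09  -86.05     False
best fit: PA3 (AIC 178.1) -- matches the planted synergy
  fixed PA effect: beta = -0.45 (ICC 0.00, pseudo-R2 fixed 0.11,
  LRT p = 2.507e-06, Bonferroni-significant: True)
```

The cohort generator planted a negative effect of push-off control on DP;
the pipeline identifies the push-off synergy as the best model for both DP
and DP x NJI, with the expected sign.

A command-line interface mirrors the library
(`kinesynergy simulate|pm|events|dp|fit|run`), e.g.
`kinesynergy run --config pipeline.yaml`.

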