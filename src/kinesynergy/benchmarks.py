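"""End-to-end recovery benchmarks on synthetic gait with known ground truth.

Each function builds its own inputs from the simulator, runs the relevant
part of the analysis pipeline, and returns the measured quantities as a flat
dict.  The test suite asserts tolerances on these numbers; the acceptance
script reports them.  Problem sizes are chosen so every benchmark completes
in minutes on one core (the methods note lists them).
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from .coordination import crp, phase_angle, trial_dp
from .events import detect_heel_strikes
from .models import ModelSpec, compare_models, fit_mixed, stepwise_eliminate
from .pipeline import PipelineConfig, run_pipeline
from .posture import (
    build_posture_matrix,
    compute_pms,
    differentiate_scores,
    loo_validate,
    pa_rms,
    subspace_angles_deg,
)
from .simulate import (
    GaitSimConfig,
    generate_trial,
    random_synergy_basis,
    simulate_model_dataset,
)
from .smoothness import nji

__all__ = [
    "crp_plateau_benchmark",
    "dp_recovery_benchmark",
    "pa_rms_closed_form_benchmark",
    "synergy_recovery_benchmark",
    "loo_validation_benchmark",
    "nji_closed_form_benchmark",
    "heel_strike_benchmark",
    "mixed_model_recovery_benchmark",
    "stepwise_elimination_benchmark",
    "pipeline_determinism_benchmark",
]


def crp_plateau_benchmark(seed: int = 0) -> dict[str, float]:
    """Hilbert-CRP of two sinusoids with a 60-degree lag, plus the deviation
    phase of a jitter-free simulated trial (should be ~0)."""
    fs, f, lag = 100.0, 1.0, 60.0
    t = np.arange(0, 60.0, 1.0 / fs)
    prox = np.sin(2 * np.pi * f * t)
    dist = np.sin(2 * np.pi * f * t - np.deg2rad(lag))
    series = crp(phase_angle(prox), phase_angle(dist))
    trim = int(0.10 * series.size)
    plateau = series[trim:-trim]
    cfg = GaitSimConfig(
        phase_jitter_sd_deg=0.0, noise_sd=0.0, perturbed_duration_s=60.0, seed=seed
    )
    trial, _ = generate_trial(cfg, "S01", 1.2, "perturbed")
    record, _ = trial_dp(trial)
    return dict(
        plateau_mean_deg=float(plateau.mean()),
        plateau_max_abs_err_deg=float(np.max(np.abs(plateau - lag))),
        zero_jitter_trial_dp_deg=float(record.trial_dp),
        n=int(t.size),
    )


def dp_recovery_benchmark(seed: int = 0, planted_deg: float = 5.0) -> dict[str, float]:
    """Measured trial DP against a planted per-stride phase-jitter SD over
    ~200 strides of perturbed walking."""
    cfg = GaitSimConfig(
        phase_jitter_sd_deg=planted_deg,
        noise_sd=0.0,
        perturbed_duration_s=230.0,
        seed=seed,
    )
    trial, truth = generate_trial(cfg, "S01", 1.2, "perturbed")
    record, _ = trial_dp(trial)
    n_strides = len(truth.heel_strike_times["left"]) - 1
    return dict(
        planted_dp_deg=planted_deg,
        measured_dp_deg=float(record.trial_dp),
        rel_err=float(abs(record.trial_dp - planted_deg) / planted_deg),
        n=int(n_strides),
    )


def pa_rms_closed_form_benchmark(seed: int = 0) -> dict[str, float]:
    """RMS of the second derivative of A sin(2 pi f t) against A(2 pi f)^2/sqrt(2),
    and the exactness of the speed normalization."""
    fs, f, amp = 100.0, 2.0, 3.0
    t = np.arange(0, 50.0, 1.0 / fs)
    pp = amp * np.sin(2 * np.pi * f * t)
    ts = differentiate_scores(pp, fs, prefilter=None)
    rec = pa_rms(ts.pa[:, 0], speed=1.6)
    expected = amp * (2 * np.pi * f) ** 2 / np.sqrt(2.0)
    return dict(
        measured_rms=rec.pa_rms_raw,
        expected_rms=float(expected),
        rel_err=float(abs(rec.pa_rms_raw - expected) / expected),
        norm_abs_err=float(abs(rec.pa_rms_norm - rec.pa_rms_raw / 1.6)),
        n=int(t.size),
    )


def synergy_recovery_benchmark(seed: int = 0) -> dict[str, float]:
    """Principal-movement recovery of a planted orthonormal basis with
    variance fractions (0.80, 0.15, 0.05) at SNR 100."""
    fractions = (0.80, 0.15, 0.05)
    basis = random_synergy_basis(20, 3, seed=seed)
    scale = 0.05
    # SNR: total planted deviation variance over total marker-noise variance
    noise_sd = scale / np.sqrt(100 * 3 * 20)
    cfg = GaitSimConfig(
        n_subjects=6,
        synergy_vectors=basis,
        synergy_variance_fractions=fractions,
        synergy_scale=scale,
        noise_sd=noise_sd,
        duration_s=20.0,
        stride_freq_base=1.0,
        seed=seed,
    )
    trials = [
        generate_trial(cfg, f"S{i:02d}", s, "normal")[0]
        for i in range(1, 7)
        for s in cfg.speeds
    ]
    pms = compute_pms(build_posture_matrix(trials), 3)
    angles = subspace_angles_deg(pms.eigenvectors, basis)
    frac_err = np.abs(pms.variance_fractions - np.asarray(fractions))
    return dict(
        max_angle_deg=float(angles.max()),
        max_fraction_err=float(frac_err.max()),
        n=int(sum(t.n_frames for t in trials)),
    )


def loo_validation_benchmark(seed: int = 0) -> dict[str, float]:
    """Leave-one-out PM stability on a homogeneous 6-subject cohort, then on a
    cohort where one subject's PM2/PM3 plane is rotated 45 degrees (with its
    in-plane variance share raised so the planted instability is detectable)."""
    basis = random_synergy_basis(20, 3, seed=seed)
    common = dict(
        n_subjects=6,
        synergy_scale=0.05,
        noise_sd=0.0005,
        duration_s=15.0,
        stride_freq_base=1.0,
        seed=seed,
    )
    cfg = GaitSimConfig(
        synergy_vectors=basis, synergy_variance_fractions=(0.80, 0.15, 0.05), **common
    )
    subjects = [f"S{i:02d}" for i in range(1, 7)]
    trials = [
        generate_trial(cfg, sid, s, "normal")[0] for sid in subjects for s in cfg.speeds
    ]
    homogeneous = loo_validate(trials, 3)

    theta = np.deg2rad(45.0)
    rot = basis.copy()
    rot[1] = np.cos(theta) * basis[1] + np.sin(theta) * basis[2]
    rot[2] = -np.sin(theta) * basis[1] + np.cos(theta) * basis[2]
    cfg_rot = GaitSimConfig(
        synergy_vectors=rot, synergy_variance_fractions=(0.50, 0.45, 0.05), **common
    )
    contaminated = [
        generate_trial(cfg if sid != "S06" else cfg_rot, sid, s, "normal")[0]
        for sid in subjects
        for s in cfg.speeds
    ]
    mixed = loo_validate(contaminated, 3)
    return dict(
        homogeneous_max_angle_deg=float(homogeneous.validation_angles.max()),
        homogeneous_all_validated=float(homogeneous.validated.all()),
        contaminated_pm2_angle_deg=float(mixed.validation_angles[1]),
        contaminated_pm2_validated=float(mixed.validated[1]),
        contaminated_pm1_angle_deg=float(mixed.validation_angles[0]),
        n=int(len(trials)),
    )


def nji_closed_form_benchmark(seed: int = 0) -> dict[str, float]:
    """NJI of A sin(2 pi t) against the closed form 8 pi, its amplitude
    independence, and NJI of a constant-velocity line."""
    fs = 100.0
    t = np.arange(0, 10.0, 1.0 / fs)
    records = []
    for amp in (0.5, 2.0):
        traj = np.column_stack(
            [amp * np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)]
        )
        records.append(nji(traj, fs).nji)
    expected = 8 * np.pi
    line = np.column_stack([0.3 * t, 0.1 * t, np.zeros_like(t)])
    return dict(
        measured_nji=float(records[0]),
        expected_nji=float(expected),
        rel_err=float(max(abs(r - expected) / expected for r in records)),
        amplitude_dependence=float(abs(records[0] - records[1]) / expected),
        line_nji=float(nji(line, fs).nji),
        n=int(t.size),
    )


def heel_strike_benchmark(seed: int = 0) -> dict[str, float]:
    """Detector agreement with planted heel strikes on noise-free trials."""
    cfg = GaitSimConfig(
        phase_jitter_sd_deg=0.0, noise_sd=0.0, perturbed_duration_s=60.0, seed=seed
    )
    max_err = 0
    count_err = 0
    n_events = 0
    for speed in cfg.speeds:
        trial, truth = generate_trial(cfg, "S01", speed, "perturbed")
        for side in ("left", "right"):
            events = detect_heel_strikes(trial, side)
            planted = np.round(truth.heel_strike_times[side] * trial.fs).astype(int)
            detected = events.heel_strike_frames
            count_err = max(count_err, abs(len(detected) - len(planted)))
            n_common = min(len(detected), len(planted))
            max_err = max(
                max_err, int(np.max(np.abs(detected[:n_common] - planted[:n_common])))
            )
            n_events += len(planted)
            expected_count = trial.n_frames / trial.fs * cfg.stride_frequency(speed)
            count_err = max(count_err, int(abs(len(detected) - round(expected_count))))
    return dict(
        max_frame_err=float(max_err), max_count_err=float(count_err), n=int(n_events)
    )


_TRUTH = dict(beta=-2.18, intercept=46.0, re_int_var=3.08, re_slope_sd=0.3, resid_var=3.84)


def mixed_model_recovery_benchmark(seed: int = 0, n_rep: int = 100) -> dict[str, float]:
    """Parameter recovery of the final DP ~ PA + (PA | participant) structure
    over ``n_rep`` cohorts of 13 subjects x 3 speeds."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xBE7A])
    truth_icc = _TRUTH["re_int_var"] / (_TRUTH["re_int_var"] + _TRUTH["resid_var"])
    betas, iccs, covered = [], [], 0
    spec = ModelSpec(
        "DP",
        "PA4",
        fixed_terms=("PA",),
        random_terms=("participant_intercept", "participant_slope"),
    )
    for _ in range(n_rep):
        df = simulate_model_dataset(
            beta=_TRUTH["beta"],
            intercept=_TRUTH["intercept"],
            re_intercept_sd=np.sqrt(_TRUTH["re_int_var"]),
            re_slope_sd=_TRUTH["re_slope_sd"],
            resid_sd=np.sqrt(_TRUTH["resid_var"]),
            seed=rng,
        ).rename(columns={"pa": "PA4", "dp": "DP"})
        fit = fit_mixed(spec, df)
        beta, se = float(fit.fe_params["pa"]), float(fit.fe_bse["pa"])
        betas.append(beta)
        iccs.append(fit.icc)
        if se > 0 and beta - 1.96 * se <= _TRUTH["beta"] <= beta + 1.96 * se:
            covered += 1
    return dict(
        beta_mean=float(np.mean(betas)),
        beta_rel_err=float(abs(np.mean(betas) - _TRUTH["beta"]) / abs(_TRUTH["beta"])),
        coverage=float(covered / n_rep),
        icc_mean=float(np.mean(iccs)),
        icc_abs_err=float(abs(np.mean(iccs) - truth_icc)),
        n=int(n_rep),
    )


def stepwise_elimination_benchmark(seed: int = 0, n_rep: int = 100) -> dict[str, float]:
    """Behavior of stepwise elimination on cohorts where walking speed, the
    interaction and all random slopes have zero generating effect.

    Reports per-term and pooled elimination rates of the zero-effect terms,
    the retention rate of the real terms (PA fixed effect, participant
    intercept), the worst AIC/BIC identity error over all final fits, and the
    self-comparison chi-square/p.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x57E9])
    null_terms = ("PA:Trial", "Trial", "participant_slope", "trial_intercept", "trial_slope")
    removed = dict.fromkeys(null_terms, 0)
    kept_pa = kept_int = 0
    max_identity_err = 0.0
    for _ in range(n_rep):
        df = simulate_model_dataset(re_slope_sd=0.0, seed=rng).rename(
            columns={"pa": "PA4", "dp": "DP"}
        )
        final_spec, _ = stepwise_eliminate(ModelSpec("DP", "PA4"), df)
        in_model = set(final_spec.fixed_terms) | set(final_spec.random_terms)
        for term in null_terms:
            removed[term] += term not in in_model
        kept_pa += "PA" in final_spec.fixed_terms
        kept_int += "participant_intercept" in final_spec.random_terms
        fit = fit_mixed(final_spec, df)
        max_identity_err = max(
            max_identity_err,
            abs(fit.aic - (-2 * fit.llf_ml + 2 * fit.df)),
            abs(fit.bic - (-2 * fit.llf_ml + fit.df * np.log(fit.n))),
        )
    rates = {f"removed_{t}": v / n_rep for t, v in removed.items()}
    df0 = simulate_model_dataset(seed=rng).rename(columns={"pa": "PA4", "dp": "DP"})
    m = fit_mixed(
        ModelSpec("DP", "PA4", fixed_terms=("PA",), random_terms=("participant_intercept",)),
        df0,
    )
    self_cmp = compare_models([m, m])
    return dict(
        pooled_elimination_rate=float(sum(removed.values()) / (n_rep * len(null_terms))),
        **{k: float(v) for k, v in rates.items()},
        kept_pa_rate=float(kept_pa / n_rep),
        kept_participant_intercept_rate=float(kept_int / n_rep),
        aic_bic_identity_max_err=float(max_identity_err),
        self_comparison_chisq=float(self_cmp["chisq"].iloc[1]),
        self_comparison_p=float(self_cmp["p"].iloc[1]),
        n=int(n_rep),
    )


def _small_pipeline_config(seed: int, out_dir: str | Path) -> PipelineConfig:
    sim = GaitSimConfig(
        n_subjects=5,
        duration_s=15.0,
        perturbed_duration_s=40.0,
        noise_sd=0.002,
        seed=seed,
    )
    return PipelineConfig(
        sim=sim,
        n_resample=1500,
        k_max=3,
        validate_pms=False,
        responses=("DP",),
        random_trial_terms=False,
        out_dir=str(out_dir),
    )


def pipeline_determinism_benchmark(seed: int, scratch_dir: str | Path) -> dict[str, float]:
    """Run the full pipeline twice with one seed and compare output bytes."""
    scratch_dir = Path(scratch_dir)
    dirs = [scratch_dir / "run_a", scratch_dir / "run_b"]
    for d in dirs:
        run_pipeline(_small_pipeline_config(seed, d))
    names = sorted(p.name for p in dirs[0].iterdir())
    names_b = sorted(p.name for p in dirs[1].iterdir())
    identical = names == names_b and all(
        filecmp.cmp(dirs[0] / n, dirs[1] / n, shallow=False) for n in names
    )
    return dict(identical=float(identical), n=int(len(names)))
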