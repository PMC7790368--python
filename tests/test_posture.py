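import numpy as np
import pytest

from kinesynergy.io import MarkerTrial
from kinesynergy.posture import (
    build_posture_matrix,
    compute_pms,
    differentiate_scores,
    loo_validate,
    pa_rms,
    project_scores,
    spectral_noise_check,
    subspace_angles_deg,
)


def _trial(data, subject="S01", speed=1.2, fs=100.0):
    data = np.asarray(data, dtype=float)
    labels = [f"M{i}" for i in range(data.shape[1])]
    return MarkerTrial(
        subject_id=subject, condition="normal", speed=speed, fs=fs,
        labels=labels, data=data,
    )


class TestPostureMatrix:
    def test_static_trial_gives_zero_rows(self, rng):
        frame = rng.normal(size=(1, 4, 3))
        t = _trial(np.repeat(frame, 10, axis=0))
        mat = build_posture_matrix([t])
        np.testing.assert_allclose(mat.values, 0.0, atol=1e-12)

    def test_mean_row_norm_is_one_per_trial(self, rng):
        trials = [
            _trial(rng.normal(size=(50, 5, 3)), subject=f"S{i}") for i in range(3)
        ]
        mat = build_posture_matrix(trials)
        for key in mat.trial_index:
            norms = np.linalg.norm(mat.rows(key), axis=1)
            assert norms.mean() == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_example(self):
        # 2 trials x 4 frames x 2 markers, worked independently below
        d1 = np.array(
            [
                [[0.0, 0.0, 1.0], [0.0, 0.0, 0.0]],
                [[0.2, 0.0, 1.0], [0.0, 0.0, 0.0]],
                [[0.0, 0.2, 1.0], [0.0, 0.0, 0.2]],
                [[0.2, 0.2, 1.0], [0.0, 0.0, 0.2]],
            ]
        )
        d2 = d1[::-1] * 1.5
        trials = [_trial(d1, subject="A"), _trial(d2, subject="B")]
        mat = build_posture_matrix(trials)
        for data, key in ((d1, ("A", 1.2, "normal")), (d2, ("B", 1.2, "normal"))):
            com = data.mean(axis=1, keepdims=True)  # frames x 1 x 3
            cen = (data - com).reshape(4, 6)
            dev = cen - cen.mean(axis=0)
            dbar = np.linalg.norm(dev, axis=1).mean()
            np.testing.assert_allclose(mat.rows(key), dev / dbar, atol=1e-12)

    def test_mismatched_marker_sets_rejected(self, rng):
        a = _trial(rng.normal(size=(10, 3, 3)), subject="A")
        b = _trial(rng.normal(size=(10, 4, 3)), subject="B")
        with pytest.raises(ValueError, match="mismatch"):
            build_posture_matrix([a, b])


class TestComputePMs:
    def test_rank_one_motion_recovers_the_direction(self, rng):
        v = rng.normal(size=12)
        scores = np.sin(np.linspace(0, 6 * np.pi, 200))
        base = rng.normal(size=12)
        data = (base + np.outer(scores, v)).reshape(200, 4, 3)
        mat = build_posture_matrix([_trial(data)])
        with pytest.warns(UserWarning, match="rank"):
            pms = compute_pms(mat, 3)
        assert pms.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_planted_fraction_recovery(self, lowrank_trials, planted_basis):
        _, trials = lowrank_trials
        pms = compute_pms(build_posture_matrix(trials), 3)
        np.testing.assert_allclose(
            pms.variance_fractions, (0.80, 0.15, 0.05), atol=0.02
        )
        assert subspace_angles_deg(pms.eigenvectors, planted_basis).max() < 2.0

    def test_eigenvalues_conserve_total_variance(self, lowrank_trials):
        _, trials = lowrank_trials
        mat = build_posture_matrix(trials)
        with pytest.warns(UserWarning, match="rank"):
            pms = compute_pms(mat, 60)
        # rows are centered per trial, so the SVD spectrum carries all variance
        total = (mat.values**2).sum() / (mat.values.shape[0] - 1)
        assert pms.eigenvalues.sum() == pytest.approx(pms.total_variance, rel=1e-8)
        assert pms.total_variance == pytest.approx(total, rel=1e-6)

    def test_fractions_descending_and_vectors_orthonormal(self, lowrank_trials):
        _, trials = lowrank_trials
        pms = compute_pms(build_posture_matrix(trials), 3)
        assert np.all(np.diff(pms.variance_fractions) <= 0)
        np.testing.assert_allclose(
            pms.eigenvectors @ pms.eigenvectors.T, np.eye(3), atol=1e-8
        )

    def test_sign_convention_largest_loading_positive(self, lowrank_trials):
        _, trials = lowrank_trials
        pms = compute_pms(build_posture_matrix(trials), 3)
        for v in pms.eigenvectors:
            assert v[np.argmax(np.abs(v))] > 0


class TestProjection:
    def test_projection_reconstructs_rows(self, lowrank_trials):
        _, trials = lowrank_trials
        mat = build_posture_matrix(trials)
        with pytest.warns(UserWarning, match="rank"):
            pms = compute_pms(mat, 10)
        key = trials[0].key
        pp = project_scores(pms, mat, key)
        recon = pp @ pms.eigenvectors
        assert np.abs(recon - mat.rows(key)).max() < 1e-10

    def test_scores_of_distinct_pms_are_uncorrelated(self, lowrank_trials):
        _, trials = lowrank_trials
        mat = build_posture_matrix(trials)
        pms = compute_pms(mat, 3)
        pp = project_scores(pms, mat, trials[3].key)
        corr = np.corrcoef(pp.T)
        assert np.abs(corr - np.eye(3)).max() < 0.02

    def test_unknown_trial_key_rejected(self, lowrank_trials):
        _, trials = lowrank_trials
        mat = build_posture_matrix(trials)
        pms = compute_pms(mat, 2)
        with pytest.raises(KeyError):
            project_scores(pms, mat, ("nobody", 9.9, "normal"))


class TestDifferentiation:
    def test_constant_scores_have_zero_derivatives(self):
        ts = differentiate_scores(np.full(200, 2.5), 100.0)
        np.testing.assert_allclose(ts.pv, 0.0, atol=1e-9)
        np.testing.assert_allclose(ts.pa, 0.0, atol=1e-9)

    def test_sine_second_derivative_closed_form(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        pp = np.sin(2 * np.pi * 1.0 * t)
        ts = differentiate_scores(pp, fs, prefilter=None)
        expected = -((2 * np.pi) ** 2) * np.sin(2 * np.pi * t)
        mid = slice(200, 800)
        err = np.abs(ts.pa[mid, 0] - expected[mid]).max()
        assert err < 0.01 * (2 * np.pi) ** 2

    def test_differentiation_is_homogeneous(self, rng):
        pp = rng.normal(size=300)
        a = differentiate_scores(3.5 * pp, 100.0)
        b = differentiate_scores(pp, 100.0)
        np.testing.assert_allclose(a.pa, 3.5 * b.pa, atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="5"):
            differentiate_scores(np.ones(4), 100.0)


class TestSpectralCheck:
    def test_band_limited_signal_passes(self):
        t = np.arange(0, 20, 0.01)
        rep = spectral_noise_check(np.sin(2 * np.pi * 1.0 * t), 100.0)
        assert rep.fraction_above < 1e-6 and rep.passed

    def test_high_frequency_signal_fails(self):
        t = np.arange(0, 20, 0.01)
        rep = spectral_noise_check(np.sin(2 * np.pi * 8.0 * t), 100.0)
        assert rep.fraction_above > 0.99 and not rep.passed

    def test_two_tone_fraction_matches_parseval(self):
        t = np.arange(0, 50, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t) + 0.1 * np.sin(2 * np.pi * 8.0 * t)
        rep = spectral_noise_check(x, 100.0)
        assert rep.fraction_above == pytest.approx(0.01 / 1.01, rel=0.10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="64"):
            spectral_noise_check(np.ones(63), 100.0)


class TestPARMS:
    def test_constant_acceleration_rms_is_magnitude(self):
        rec = pa_rms(np.full(100, -3.0), speed=1.2)
        assert rec.pa_rms_raw == pytest.approx(3.0)

    def test_speed_normalization_is_exact_division(self):
        rec = pa_rms(np.ones(10) * 4.0, speed=1.6)
        assert rec.pa_rms_norm == rec.pa_rms_raw / 1.6

    def test_scaling_speeds_rescales_normalized_values(self, rng):
        pa = rng.normal(size=500)
        r1 = pa_rms(pa, speed=0.8)
        r2 = pa_rms(pa, speed=0.8 * 2.0)
        assert r2.pa_rms_norm == pytest.approx(r1.pa_rms_norm / 2.0)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            pa_rms(np.ones(5), speed=0.0)


class TestLeaveOneOut:
    def test_homogeneous_cohort_fully_validated(self, lowrank_trials):
        _, trials = lowrank_trials
        pms = loo_validate(trials, 3)
        assert pms.validation_angles.max() < 1e-2
        assert pms.validated.all()

    def test_rotated_subject_invalidates_pm2_only(self, planted_basis):
        from kinesynergy import GaitSimConfig, generate_trial

        theta = np.deg2rad(45.0)
        rot = planted_basis.copy()
        rot[1] = np.cos(theta) * planted_basis[1] + np.sin(theta) * planted_basis[2]
        rot[2] = -np.sin(theta) * planted_basis[1] + np.cos(theta) * planted_basis[2]
        common = dict(noise_sd=0.0, duration_s=10.0, stride_freq_base=1.0, seed=5)
        cfg = GaitSimConfig(
            synergy_vectors=planted_basis,
            synergy_variance_fractions=(0.80, 0.15, 0.05),
            **common,
        )
        cfg_rot = GaitSimConfig(
            synergy_vectors=rot, synergy_variance_fractions=(0.50, 0.45, 0.05), **common
        )
        trials = [
            generate_trial(cfg if i < 6 else cfg_rot, f"S{i:02d}", s, "normal")[0]
            for i in range(1, 7)
            for s in cfg.speeds
        ]
        pms = loo_validate(trials, 3)
        assert pms.validation_angles[1] > 15.0 and not pms.validated[1]
        assert pms.validation_angles[0] < 5.0 and pms.validated[0]

    def test_threshold_is_strict_less_than(self, lowrank_trials):
        _, trials = lowrank_trials
        pms = loo_validate(trials, 2)
        boundary = float(pms.validation_angles[0])
        at = loo_validate(trials, 2, angle_threshold_deg=boundary)
        above = loo_validate(trials, 2, angle_threshold_deg=boundary * (1 + 1e-9) + 1e-12)
        assert not at.validated[0]  # angle == threshold -> not validated
        assert above.validated[0]

    def test_fewer_than_three_subjects_rejected(self, lowrank_trials):
        _, trials = lowrank_trials
        two = [t for t in trials if t.subject_id in ("S01", "S02")]
        with pytest.raises(ValueError, match="3 subjects"):
            loo_validate(two, 2)
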