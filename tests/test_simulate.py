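import numpy as np
import pytest

from kinesynergy import (
    GaitSimConfig,
    generate_cohort,
    generate_trial,
    random_synergy_basis,
    simulate_model_dataset,
)
from kinesynergy.simulate import SimulationError, bounce_direction


class TestConfigValidation:
    def test_non_orthonormal_synergy_set_rejected(self):
        bad = np.array([[1.0, 0.0, 0.0, 0.0, 0.0, 0.0], [0.9, 0.1, 0.0, 0.0, 0.0, 0.0]])
        with pytest.raises(SimulationError, match="orthonormal"):
            GaitSimConfig(synergy_vectors=bad, synergy_variance_fractions=(0.8, 0.2))

    def test_low_sampling_rate_rejected_as_aliasing(self):
        with pytest.raises(SimulationError, match="alias"):
            GaitSimConfig(fs=10.0)

    def test_unsorted_fractions_rejected(self):
        basis = random_synergy_basis(20, 2, seed=0)
        with pytest.raises(SimulationError, match="descending"):
            GaitSimConfig(synergy_vectors=basis, synergy_variance_fractions=(0.2, 0.8))

    def test_unknown_speed_rejected(self):
        cfg = GaitSimConfig()
        with pytest.raises(SimulationError, match="speed"):
            generate_trial(cfg, "S01", 2.4, "normal")


class TestDeterminismAndPeriodicity:
    def test_same_seed_gives_bit_identical_trials(self):
        cfg = GaitSimConfig(noise_sd=0.002, duration_s=5.0, seed=3)
        a, _ = generate_trial(cfg, "S05", 0.8, "normal")
        b, _ = generate_trial(cfg, "S05", 0.8, "normal")
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_subjects_differ(self):
        cfg = GaitSimConfig(noise_sd=0.002, duration_s=5.0, seed=3)
        a, _ = generate_trial(cfg, "S05", 0.8, "normal")
        b, _ = generate_trial(cfg, "S06", 0.8, "normal")
        assert not np.array_equal(a.data, b.data)

    def test_zero_noise_zero_jitter_trials_are_stride_periodic(self, clean_trial):
        # stride frequency 1 Hz at fs 100 -> period = exactly 100 frames
        trial, _ = clean_trial
        diff = np.abs(trial.data[100:200] - trial.data[0:100])
        assert diff.max() < 1e-9


class TestLowRankMode:
    def test_planted_covariance_rank_and_fractions(self, planted_basis):
        cfg = GaitSimConfig(
            synergy_vectors=planted_basis,
            synergy_variance_fractions=(0.80, 0.15, 0.05),
            noise_sd=0.0,
            duration_s=50.0,
            stride_freq_base=1.0,
        )
        trial, _ = generate_trial(cfg, "S01", 1.2, "normal")
        dev = trial.data.reshape(trial.n_frames, -1)
        dev = dev - dev.mean(axis=0)
        s = np.linalg.svd(dev, compute_uv=False)
        lam = s**2 / (trial.n_frames - 1)
        assert (lam > lam[0] * 1e-12).sum() == 3
        np.testing.assert_allclose(
            lam[:3] / lam.sum(), (0.80, 0.15, 0.05), atol=0.02 * 0.80
        )

    def test_deviations_lie_in_planted_span(self, planted_basis):
        cfg = GaitSimConfig(
            synergy_vectors=planted_basis,
            synergy_variance_fractions=(0.80, 0.15, 0.05),
            noise_sd=0.0,
            duration_s=10.0,
            stride_freq_base=1.0,
        )
        trial, truth = generate_trial(cfg, "S01", 1.2, "normal")
        dev = trial.data.reshape(trial.n_frames, -1)
        dev = dev - dev.mean(axis=0)
        resid = dev - (dev @ planted_basis.T) @ planted_basis
        assert np.abs(resid).max() < 1e-9
        np.testing.assert_array_equal(truth.synergy_basis, planted_basis)

    def test_zero_noise_variance_conservation(self, planted_basis):
        # total posture-deviation variance equals the sum of planted variances
        cfg = GaitSimConfig(
            synergy_vectors=planted_basis,
            synergy_variance_fractions=(0.80, 0.15, 0.05),
            synergy_scale=0.05,
            noise_sd=0.0,
            duration_s=50.0,
            stride_freq_base=1.0,
        )
        trial, _ = generate_trial(cfg, "S01", 1.2, "normal")
        dev = trial.data.reshape(trial.n_frames, -1)
        dev = dev - dev.mean(axis=0)
        total = dev.var(axis=0).sum()
        planted = 0.05**2 * (0.80 + 0.15 + 0.05)
        assert abs(total - planted) / planted < 1e-6


class TestGroundTruth:
    def test_heel_strike_times_strictly_increasing(self, clean_perturbed):
        _, truth = clean_perturbed
        for side in ("left", "right"):
            assert np.all(np.diff(truth.heel_strike_times[side]) > 0)

    def test_planted_pair_lags_have_configured_spread(self):
        cfg = GaitSimConfig(
            phase_jitter_sd_deg=5.0, noise_sd=0.0, perturbed_duration_s=480.0, seed=0
        )
        _, truth = generate_trial(cfg, "S01", 1.2, "perturbed")
        sds = [np.std(v, ddof=1) for v in truth.true_phase_lag.values()]
        assert np.mean(sds) == pytest.approx(5.0, rel=0.10)
        assert truth.true_dp == 5.0

    def test_bounce_direction_is_com_free_unit_vector(self):
        v = bounce_direction()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        for ax in range(3):
            assert abs(v[ax::3].sum()) < 1e-12


class TestCohort:
    def test_cohort_counts(self):
        cfg = GaitSimConfig(
            n_subjects=13, duration_s=2.0, perturbed_duration_s=3.0, seed=1
        )
        cohort, truth = generate_cohort(cfg)
        assert len(cohort) == 13 * 3 * 2
        assert len(truth) == 13 * 3
        assert truth["subject"].nunique() == 13

    def test_degenerate_random_effects_share_one_generating_line(self):
        cfg = GaitSimConfig(
            n_subjects=4,
            duration_s=2.0,
            perturbed_duration_s=3.0,
            re_intercept_sd=0.0,
            re_slope_sd=0.0,
            seed=1,
        )
        _, truth = generate_cohort(cfg)
        assert (truth["b0"] == 0).all() and (truth["b1"] == 0).all()

    def test_single_subject_cohort_rejected(self):
        cfg = GaitSimConfig(n_subjects=1, duration_s=2.0, perturbed_duration_s=3.0)
        with pytest.raises(SimulationError, match="2 subjects"):
            generate_cohort(cfg)


class TestModelDatasetGenerator:
    def test_intercept_sd_recovered_over_many_subjects(self):
        # Monte-Carlo check of the stated sampling distribution
        df = simulate_model_dataset(n_subjects=500, re_intercept_sd=1.75, seed=9)
        sd = df.groupby("subject")["b0"].first().std()
        assert sd == pytest.approx(1.75, rel=0.10)

    def test_row_count_and_columns(self):
        df = simulate_model_dataset(n_subjects=13, seed=0)
        assert len(df) == 39
        assert {"subject", "trial", "pa", "dp"} <= set(df.columns)

    def test_generating_identity_holds_rowwise(self):
        df = simulate_model_dataset(
            n_subjects=5, resid_sd=0.0, beta=-2.0, intercept=40.0, seed=2
        )
        pred = 40.0 + df.b0 + (-2.0 + df.b1) * df.pa
        np.testing.assert_allclose(df.dp, pred, atol=1e-12)
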