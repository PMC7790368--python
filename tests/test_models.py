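import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from kinesynergy import simulate_model_dataset
from kinesynergy.coordination import DPRecord
from kinesynergy.models import (
    FittedModel,
    ModelFitError,
    ModelSpec,
    assemble_dataset,
    bonferroni_gate,
    compare_models,
    fit_mixed,
    model_indices,
    stepwise_eliminate,
)
from kinesynergy.posture import PARMSRecord
from kinesynergy.smoothness import NJIRecord


def _dataset(seed=0, **kw):
    return simulate_model_dataset(seed=seed, **kw).rename(
        columns={"pa": "PA4", "dp": "DP"}
    )


INT_SPEC = ModelSpec(
    "DP", "PA4", fixed_terms=("PA",), random_terms=("participant_intercept",)
)


class TestAssemble:
    def _records(self, n_subj=13, speeds=(0.8, 1.2, 1.6), ks=(1, 2)):
        pa, dp, nj = [], [], []
        for i in range(n_subj):
            s_id = f"S{i:02d}"
            for s in speeds:
                for k in ks:
                    pa.append(PARMSRecord(s_id, s, k, 10.0 * k, 10.0 * k / s))
                rec = DPRecord(s_id, s)
                rec.pair_dp[("hip", "knee", "left")] = 25.0
                dp.append(rec)
                nj.append(NJIRecord(s_id, s, "right", 1.0, 1.0, 0.2))
        return pa, dp, nj

    def test_thirteen_by_three_gives_39_rows(self):
        table = assemble_dataset(*self._records())
        assert len(table) == 39
        assert {"PA1_RMS_norm", "PA2_RMS_norm", "DP", "NJI", "DPxNJI"} <= set(table)

    def test_response_product_column(self):
        table = assemble_dataset(*self._records())
        np.testing.assert_allclose(table["DPxNJI"], table["DP"] * table["NJI"])
        assert table["DPxNJI"].iloc[0] == pytest.approx(5.0)

    def test_duplicate_cell_rejected(self):
        pa, dp, nj = self._records()
        dp.append(dp[0])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_dataset(pa, dp, nj)

    def test_missing_cell_listed(self):
        pa, dp, nj = self._records()
        with pytest.raises(ValueError, match="S00"):
            assemble_dataset(pa, dp[1:], nj)

    def test_trial_factor_is_ordered_speed(self):
        table = assemble_dataset(*self._records())
        assert list(table["trial"].cat.categories) == ["0.8", "1.2", "1.6"]


class TestFitMixed:
    def test_aic_bic_identities_hold_for_every_structure(self):
        df = _dataset(seed=4)
        specs = [
            ModelSpec("DP", "PA4", fixed_terms=("PA",), random_terms=()),
            INT_SPEC,
            ModelSpec(
                "DP", "PA4", fixed_terms=("PA",),
                random_terms=("participant_intercept", "participant_slope"),
            ),
            ModelSpec("DP", "PA4"),  # maximal crossed
        ]
        for spec in specs:
            m = fit_mixed(spec, df)
            assert m.aic == pytest.approx(-2 * m.llf_ml + 2 * m.df, abs=1e-10)
            assert m.bic == pytest.approx(-2 * m.llf_ml + m.df * np.log(m.n), abs=1e-10)

    def test_zero_random_variance_cohorts_have_small_icc(self):
        # REML variance estimates are nonnegative, so their mean on null data
        # sits slightly above zero (lme4 shows the same positive-part bias at
        # this n); the mean ICC must stay well below the moderate-clustering
        # regime and beta must stay unbiased
        iccs, errs = [], []
        for rep in range(20):
            df = _dataset(seed=500 + rep, re_intercept_sd=0.0, re_slope_sd=0.0)
            m = fit_mixed(INT_SPEC, df)
            iccs.append(m.icc)
            errs.append((m.fe_params["pa"] + 2.18) / m.fe_bse["pa"])
        assert np.mean(iccs) < 0.15
        assert abs(np.mean(errs)) < 2.0  # beta within 2 SE of truth on average

    def test_constant_response_rejected(self):
        df = _dataset(seed=0)
        df["DP"] = 5.0
        with pytest.raises(ModelFitError, match="constant"):
            fit_mixed(INT_SPEC, df)

    def test_slope_requires_intercept_in_spec(self):
        with pytest.raises(ValueError, match="intercept"):
            ModelSpec("DP", "PA4", random_terms=("participant_slope",))

    def test_degrees_of_freedom_match_lmer_conventions(self):
        df = _dataset(seed=4)
        assert fit_mixed(INT_SPEC, df).df == 4  # 2 fe + 1 var + resid
        slope = ModelSpec(
            "DP", "PA4", fixed_terms=("PA",),
            random_terms=("participant_intercept", "participant_slope"),
        )
        assert fit_mixed(slope, df).df == 6  # 2 fe + (2 var + cov) + resid


@pytest.fixture(scope="module")
def fits(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("lme4")
    df = _dataset(seed=11)
    df.to_csv(tmp / "data.csv", index=False)
    script = tmp / "fit.R"
    script.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(file.path(commandArgs(TRUE)[1], "data.csv"))
        m <- lmer(DP ~ PA4 + (1 | subject), data = d, REML = TRUE)
        vc <- as.data.frame(VarCorr(m))
        out <- list(
          beta = unname(fixef(m)),
          se = unname(coef(summary(m))[, "Std. Error"]),
          var_int = vc$vcov[1], var_resid = vc$vcov[2],
          llf_reml = as.numeric(logLik(m)),
          llf_ml = as.numeric(logLik(refitML(m)))
        )
        cat(jsonlite::toJSON(out, digits = 12))
        """
    )
    r = subprocess.run(
        ["Rscript", str(script), str(tmp)], capture_output=True, text=True
    )
    assert r.returncode == 0, r.stderr
    oracle = json.loads(r.stdout)
    ours = fit_mixed(INT_SPEC, df)
    return oracle, ours


class TestAgainstLme4:
    """Independent oracle: the same random-intercept model fit by R lme4."""

    def test_fixed_effects_match(self, fits):
        oracle, ours = fits
        np.testing.assert_allclose(
            [ours.fe_params["Intercept"], ours.fe_params["pa"]],
            oracle["beta"], rtol=1e-5,
        )
        np.testing.assert_allclose(
            [ours.fe_bse["Intercept"], ours.fe_bse["pa"]], oracle["se"], rtol=0.02
        )

    def test_variance_components_match(self, fits):
        oracle, ours = fits
        assert ours.vcomps["participant_intercept"] == pytest.approx(
            oracle["var_int"][0], rel=1e-3
        )
        assert ours.resid_var == pytest.approx(oracle["var_resid"][0], rel=1e-3)

    def test_likelihoods_match(self, fits):
        oracle, ours = fits
        assert ours.llf_reml == pytest.approx(oracle["llf_reml"][0], abs=1e-4)
        assert ours.llf_ml == pytest.approx(oracle["llf_ml"][0], abs=1e-4)


class TestStepwise:
    def test_intercept_is_never_eliminated(self):
        df = _dataset(seed=6)
        final, log = stepwise_eliminate(ModelSpec("DP", "PA4"), df)
        # the fixed intercept is implicit and untouchable; the log never
        # proposes it
        assert "intercept" not in set(log["term"].str.lower())

    def test_interaction_tested_before_main_effects(self):
        df = _dataset(seed=6)
        _, log = stepwise_eliminate(ModelSpec("DP", "PA4"), df)
        fixed = log[log["phase"] == "fixed"]["term"].tolist()
        if "Trial" in fixed and "PA:Trial" in fixed:
            assert fixed.index("PA:Trial") < fixed.index("Trial")

    def test_random_slopes_removed_before_their_intercepts(self):
        df = _dataset(seed=6)
        _, log = stepwise_eliminate(ModelSpec("DP", "PA4"), df)
        rand = log[log["phase"] == "random"]["term"].tolist()
        if "trial_intercept" in rand and "trial_slope" in rand:
            assert rand.index("trial_slope") < rand.index("trial_intercept")

    def test_strong_fixed_effects_are_retained(self):
        kept = 0
        for rep in range(8):
            df = _dataset(seed=700 + rep)
            # inject a strong speed effect and interaction
            bump = df["trial"].map({"0.8": 0.0, "1.2": 12.0, "1.6": 24.0})
            df["DP"] = df["DP"] + bump + 2.0 * df["PA4"] * (df["trial"] == "1.6")
            final, _ = stepwise_eliminate(
                ModelSpec(
                    "DP", "PA4",
                    random_terms=("participant_intercept", "participant_slope"),
                ),
                df,
            )
            kept += {"PA", "Trial", "PA:Trial"} <= set(final.fixed_terms)
        assert kept >= 7

    def test_true_participant_clustering_is_retained(self):
        kept = 0
        for rep in range(8):
            df = _dataset(seed=800 + rep, re_intercept_sd=4.0)
            final, _ = stepwise_eliminate(ModelSpec("DP", "PA4"), df)
            kept += "participant_intercept" in final.random_terms
        assert kept >= 7


class TestComparison:
    def test_identical_models_compare_with_zero_chisq(self):
        m = fit_mixed(INT_SPEC, _dataset(seed=1))
        table = compare_models([m, m])
        assert table["chisq"].iloc[1] == 0.0
        assert table["p"].iloc[1] == 1.0

    def test_nested_pair_gets_lrt(self):
        df = _dataset(seed=1)
        small = fit_mixed(INT_SPEC, df)
        big = fit_mixed(
            ModelSpec(
                "DP", "PA4", fixed_terms=("PA", "Trial"),
                random_terms=("participant_intercept",),
            ),
            df,
        )
        table = compare_models([small, big])
        assert table["chisq"].iloc[1] >= 0
        assert 0 <= table["p"].iloc[1] <= 1

    def test_differing_rows_rejected(self):
        a = fit_mixed(INT_SPEC, _dataset(seed=1))
        b = fit_mixed(INT_SPEC, _dataset(seed=2))
        with pytest.raises(ValueError, match="different rows"):
            compare_models([a, b])


class TestIndices:
    def _null(self, df):
        return fit_mixed(
            ModelSpec("DP", "PA4", fixed_terms=(), random_terms=("participant_intercept",)),
            df,
        )

    def test_icc_formula_on_known_variance_components(self):
        # sigma2_int = 3.08, sigma2_res = 3.84 -> ICC = 3.08/6.92
        m = FittedModel(
            spec=INT_SPEC, n=39, fe_params=pd.Series(dtype=float),
            fe_bse=pd.Series(dtype=float), fe_pvalues=pd.Series(dtype=float),
            vcomps={"participant_intercept": 3.08}, resid_var=3.84,
            llf_reml=0.0, llf_ml=0.0, df=4, singular=False, converged=True,
        )
        assert m.icc == pytest.approx(3.08 / 6.92, abs=1e-12)

    def test_zero_intercept_variance_gives_zero_icc(self):
        m = FittedModel(
            spec=INT_SPEC, n=39, fe_params=pd.Series(dtype=float),
            fe_bse=pd.Series(dtype=float), fe_pvalues=pd.Series(dtype=float),
            vcomps={"participant_intercept": 0.0}, resid_var=3.84,
            llf_reml=0.0, llf_ml=0.0, df=4, singular=True, converged=True,
        )
        assert m.icc == 0.0

    def test_null_model_against_itself_has_zero_pseudo_r2(self):
        df = _dataset(seed=3)
        null = self._null(df)
        out = model_indices(null, null)
        assert out["pseudo_r2_fixed"] == pytest.approx(0.0, abs=1e-12)

    def test_informative_fixed_effect_gives_positive_pseudo_r2(self):
        df = _dataset(seed=3)
        m = fit_mixed(INT_SPEC, df)
        out = model_indices(m, self._null(df))
        assert out["pseudo_r2_fixed"] > 0.05
        assert out["pseudo_r2_total"] > out["pseudo_r2_fixed"] * 0.5
        assert 0 <= out["icc"] <= 1


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,expected", [(0.0069, True), (0.007, False), (0.5, False), (0.0, True)]
    )
    def test_strict_threshold(self, p, expected):
        assert bonferroni_gate([p])[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_gate([1.2])
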