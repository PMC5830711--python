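"""Mixed-model fitting, likelihood-ratio tests and Tukey comparisons."""

import numpy as np
import pandas as pd
import pytest

from countershade.glmm_analysis import (
    ModelSpec,
    fit_glmm,
    lr_test,
    read_trial_data,
    tukey_pairwise,
)
from countershade.synthetic_observer import (
    PATTERNS,
    WEATHERS,
    ObserverParams,
    TrialRecord,
    records_to_frame,
    simulate_experiment,
    write_trial_table,
)

FULL_SPEC = ModelSpec(
    response="accuracy", fixed_effects=("weather", "pattern", "session")
)
FULL_RT_SPEC = ModelSpec(
    response="rt", fixed_effects=("weather", "pattern", "session")
)

# Reference fits from lme4::glmer on the seed-42 simulated experiment
# (binomial with nAGQ=8; gamma with log link, Laplace), used as an
# independent oracle for the same models fitted here.
LME4_ACC_COEF = [2.4366783, 0.2873814, -1.8343022, -1.9440202, 0.1522742]
LME4_ACC_SE = [0.1692318, 0.1064605, 0.1702864, 0.1695645, 0.1062928]
LME4_ACC_SIGMA = 0.1182361
LME4_ACC_LOGLIK = -1072.052
LME4_RT_COEF = [0.24609914, -0.04287248, 0.73216959, 0.76926889, -0.12322982]
LME4_RT_LOGLIK = -3226.706


class TestAgainstLme4:
    def test_binomial_model_matches_glmer(self, default_records):
        res = fit_glmm(default_records, FULL_SPEC, n_quadrature=8)
        assert res.converged
        assert np.allclose(res.params, LME4_ACC_COEF, atol=1e-4)
        assert np.allclose(res.se, LME4_ACC_SE, atol=1e-3)
        assert res.sigma_u == pytest.approx(LME4_ACC_SIGMA, abs=1e-4)
        assert res.loglik == pytest.approx(LME4_ACC_LOGLIK, abs=5e-3)

    def test_gamma_model_matches_glmer_coefficients(self, default_records):
        res = fit_glmm(default_records, FULL_RT_SPEC, n_quadrature=8)
        assert res.converged
        assert np.allclose(res.params, LME4_RT_COEF, atol=5e-3)
        # joint full-ML of the shape can only improve on glmer's
        # PIRLS/deviance-based dispersion handling
        assert res.loglik >= LME4_RT_LOGLIK - 1e-6


class TestZeroVarianceLimit:
    @pytest.mark.parametrize("spec", [FULL_SPEC, FULL_RT_SPEC],
                             ids=["binomial", "gamma"])
    def test_reduces_to_ordinary_glm(self, default_records, spec):
        import statsmodels.api as sm

        res = fit_glmm(default_records, spec, fix_sigma=0.0)
        df = records_to_frame(default_records)
        X = np.column_stack(
            [
                np.ones(len(df)),
                (df.weather == "sunny").astype(float),
                (df.pattern == "cloudy_CS").astype(float),
                (df.pattern == "sunny_CS").astype(float),
                (df.session == 2).astype(float),
            ]
        )
        if spec.response == "accuracy":
            y, fam = df.correct.to_numpy(float), sm.families.Binomial()
        else:
            y = df.rt_s.to_numpy(float)
            fam = sm.families.Gamma(sm.families.links.Log())
        glm = sm.GLM(y, X, family=fam).fit()
        assert np.allclose(res.params, glm.params, rtol=1e-5, atol=1e-6)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, default_records):
        res = fit_glmm(default_records, FULL_SPEC, compute_cov=False)
        t = lr_test(res, res)
        assert t.chi_square == 0.0 and t.p_value == 1.0

    def test_pattern_drop_has_two_degrees_of_freedom(self, default_records):
        full = fit_glmm(default_records, FULL_SPEC, compute_cov=False)
        red = fit_glmm(default_records, FULL_SPEC.without("pattern"),
                       compute_cov=False)
        t = lr_test(full, red)
        assert t.df == 2
        assert t.chi_square > 0
        assert t.p_value < 1e-10  # the simulated pattern effect is large

    def test_non_nested_rejected(self, default_records):
        acc = fit_glmm(default_records, FULL_SPEC, compute_cov=False)
        rt = fit_glmm(default_records, FULL_RT_SPEC, compute_cov=False)
        with pytest.raises(ValueError):
            lr_test(acc, rt)

    def test_adding_a_factor_never_hurts_likelihood(self, default_records):
        full = fit_glmm(default_records, FULL_SPEC, compute_cov=False)
        for factor in ("weather", "pattern", "session"):
            red = fit_glmm(default_records, FULL_SPEC.without(factor),
                           compute_cov=False)
            assert full.loglik >= red.loglik - 1e-6

    def test_permuted_labels_destroy_pattern_effect(self, default_records,
                                                    rng):
        """Shuffling pattern labels should leave only chance-level
        chi-squares."""
        frame = records_to_frame(default_records)
        spec = ModelSpec(response="accuracy", fixed_effects=("pattern",))
        red = fit_glmm(frame, spec.without("pattern"), compute_cov=False)
        chis = []
        for _ in range(30):
            shuffled = frame.copy()
            shuffled["pattern"] = rng.permutation(
                shuffled["pattern"].to_numpy()
            )
            full = fit_glmm(shuffled, spec, compute_cov=False)
            chis.append(max(2 * (full.loglik - red.loglik), 0.0))
        from scipy.stats import chi2

        assert np.median(chis) < chi2.ppf(0.95, 2)


class TestQuadrature:
    def test_estimates_stable_in_node_count(self, default_records):
        r8 = fit_glmm(default_records, FULL_SPEC, n_quadrature=8,
                      compute_cov=False)
        r16 = fit_glmm(default_records, FULL_SPEC, n_quadrature=16,
                       compute_cov=False)
        assert np.max(np.abs(r16.params / r8.params - 1)) < 0.005

    def test_laplace_close_to_quadrature(self, default_records):
        r1 = fit_glmm(default_records, FULL_SPEC, n_quadrature=1,
                      compute_cov=False)
        r8 = fit_glmm(default_records, FULL_SPEC, n_quadrature=8,
                      compute_cov=False)
        assert np.allclose(r1.params, r8.params, atol=0.02)


class TestTukey:
    def test_two_level_factor_needs_no_adjustment(self, default_records):
        res = fit_glmm(default_records, FULL_SPEC)
        (pw,) = tukey_pairwise(res, "weather")
        assert pw.p_adjusted == pytest.approx(pw.p_unadjusted, abs=1e-4)

    def test_single_step_bounded_by_bonferroni(self, default_records):
        res = fit_glmm(default_records, FULL_SPEC)
        for pw in tukey_pairwise(res, "pattern"):
            assert pw.p_adjusted >= pw.p_unadjusted - 1e-12
            assert pw.p_adjusted <= min(3 * pw.p_unadjusted, 1.0) + 1e-4

    def test_deterministic_given_seed(self, default_records):
        res = fit_glmm(default_records, FULL_SPEC)
        a = tukey_pairwise(res, "pattern")
        b = tukey_pairwise(res, "pattern")
        assert [r.p_adjusted for r in a] == [r.p_adjusted for r in b]

    def test_absent_factor_rejected(self, default_records):
        res = fit_glmm(
            default_records,
            ModelSpec(response="accuracy", fixed_effects=("pattern",)),
        )
        with pytest.raises(ValueError):
            tukey_pairwise(res, "weather")


class TestParameterRecovery:
    def test_fixed_effects_recovered_without_gross_bias(self):
        """Modest replicate check; the full-scale recovery study lives in
        the acceptance suite."""
        rng = np.random.default_rng(17)
        params = ObserverParams(n_participants=25, n_sessions=2)
        spec = ModelSpec(response="rt",
                         fixed_effects=("pattern", "session"),
                         data_filter="cloudy_only")
        true = np.array(
            [
                params.rt_baseline_log_mean,
                params.rt_cell_effects[("cloudy", "cloudy_CS")],
                params.rt_cell_effects[("cloudy", "sunny_CS")],
                params.rt_session_effect,
            ]
        )
        ests = []
        for _ in range(10):
            recs = simulate_experiment(params, seed=rng)
            ests.append(
                fit_glmm(recs, spec, compute_cov=False).params.to_numpy()
            )
        bias = np.abs(np.mean(ests, axis=0) - true)
        assert np.all(bias < 0.1)

    def test_random_intercept_sd_recovered(self):
        """The correctly-specified (weather x pattern interaction) model
        recovers the generative intercept SD; the additive model would
        attenuate it by absorbing the omitted interaction."""
        rng = np.random.default_rng(23)
        params = ObserverParams(n_participants=60, n_sessions=2,
                                accuracy_intercept_sd=0.5)
        spec = ModelSpec(
            response="accuracy",
            fixed_effects=("weather", "pattern", "session"),
            interaction=True,
        )
        sigmas = [
            fit_glmm(
                simulate_experiment(params, seed=rng),
                spec,
                compute_cov=False,
            ).sigma_u
            for _ in range(6)
        ]
        assert abs(np.mean(sigmas) - 0.5) / 0.5 < 0.10


class TestValidation:
    def test_single_participant_rejected(self):
        params = ObserverParams(n_participants=1)
        recs = simulate_experiment(params, seed=0)
        with pytest.raises(ValueError):
            fit_glmm(recs, FULL_SPEC)

    def test_family_response_compatibility(self):
        with pytest.raises(ValueError):
            ModelSpec(response="accuracy", family="gamma-log")
        with pytest.raises(ValueError):
            ModelSpec(response="rt", family="binomial-logit")

    def test_gamma_inverse_link_available(self, default_records):
        spec = ModelSpec(response="rt", family="gamma-inverse",
                         fixed_effects=("pattern",))
        res = fit_glmm(default_records, spec, compute_cov=False)
        assert res.gamma_shape > 0


class TestReader:
    def test_alias_and_case_insensitive_columns(self, tmp_path):
        path = tmp_path / "renamed.csv"
        pd.DataFrame(
            {
                "Subject": [1, 1, 2, 2],
                "Session": [1, 2, 1, 2],
                "Light": ["cloudy", "sunny", "cloudy", "sunny"],
                "Reflectance": ["no_CS", "uniform", "cloudy_cs", "CS_sunny"],
                "set_size": [20, 40, 20, 40],
                "ACC": [1, 0, 1, 1],
                "Latency": [1.2, 3.4, 0.9, 2.2],
            }
        ).to_csv(path, index=False)
        table = read_trial_data(path)
        assert len(table) == 4
        assert table[1].pattern == "no_CS"
        assert table[2].pattern == "cloudy_CS"
        assert table[3].pattern == "sunny_CS"

    def test_extra_columns_preserved(self, tmp_path, default_records):
        path = tmp_path / "extra.tsv"
        frame = records_to_frame(default_records[:50])
        frame["trial_note"] = "ok"
        frame.to_csv(path, sep="\t", index=False)
        table = read_trial_data(path)
        assert list(table.extras.columns) == ["trial_note"]
        assert len(table.extras) == 50

    def test_millisecond_sniffing(self, tmp_path, default_records):
        path = tmp_path / "ms.tsv"
        frame = records_to_frame(default_records[:100])
        frame["rt_s"] = frame["rt_s"] * 1000.0
        frame.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="milliseconds"):
            flagged = read_trial_data(path)
        assert flagged.rt_in_milliseconds
        converted = read_trial_data(path, convert_ms=True)
        assert not converted.rt_in_milliseconds
        assert converted[0].rt_s == pytest.approx(default_records[0].rt_s)

    def test_seconds_not_flagged(self, tmp_path, default_records):
        path = tmp_path / "s.tsv"
        write_trial_table(default_records[:100], path)
        assert not read_trial_data(path).rt_in_milliseconds

    def test_missing_column_error_names_candidates(self, tmp_path):
        path = tmp_path / "broken.csv"
        pd.DataFrame({"participant": [1], "weird": [2]}).to_csv(
            path, index=False
        )
        with pytest.raises(ValueError, match="weird"):
            read_trial_data(path)

    def test_invalid_level_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "participant": [1],
                "session": [1],
                "weather": ["hail"],
                "pattern": ["no_CS"],
                "n_distractors": [20],
                "correct": [1],
                "rt_s": [1.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_trial_data(path)
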