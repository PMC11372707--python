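import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from forcefluct.exceptions import (
    InvalidArgumentError,
    NestingViolationError,
    RankDeficiencyError,
)
from forcefluct.inference import (
    FACTORS,
    ContrastRow,
    FitResult,
    ModelSpec,
    build_model_sequence,
    contrasts_frame,
    design_matrix,
    effect_size_r,
    fit_mixed_model,
    likelihood_ratio_test,
    select_best_model,
    stepwise_analysis,
    summarize_contrasts,
)
from forcefluct.synthetic import CohortConfig, gen_observation_table

# every printed (t, df, r) triple of the published contrast tables
TABLE2_ROWS = [
    (6.44, 553, 0.26), (5.13, 129, 0.41), (2.33, 128, 0.20),
    (-1.47, 553, 0.06), (3.34, 128, 0.28), (-0.65, 293, 0.04),
    (-0.61, 129, 0.05), (3.62, 553, 0.15),
    (66.1, 552, 0.94), (2.61, 128, 0.22), (0.83, 128, 0.07),
    (-0.89, 552, 0.04), (6.81, 128, 0.52), (-0.58, 292, 0.03),
    (-2.07, 128, 0.18), (1.47, 552, 0.06), (-4.04, 128, 0.34),
    (0.96, 292, 0.06), (2.56, 552, 0.11),
    (20.73, 553, 0.66), (-7.50, 129, 0.55), (-1.91, 128, 0.17),
    (1.45, 553, 0.06), (-1.39, 128, 0.12), (0.50, 293, 0.03),
    (2.22, 129, 0.19), (-4.28, 553, 0.18),
]


def _obs(n_subjects=10, n_per_subject=4, seed=0, value=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for j in range(n_per_subject):
            rows.append(dict(
                participant_id=f"S{i:02d}", outcome="cv",
                value=value if value is not None else rng.normal(5, 1),
                condition=("bimanual_constant", "role_differentiated")[j % 2],
                group=("CHI", "MCI")[i % 2],
                hand=("left", "right")[(j // 2) % 2],
                sex=("male", "female")[i % 3 == 0],
                timepoint=1 + (j % 2)))
    return pd.DataFrame(rows)


class TestBuildModelSequence:
    def test_first_is_intercept_only(self):
        specs = build_model_sequence()
        assert specs[0].fixed_terms == ()

    def test_two_way_count(self):
        specs = build_model_sequence()
        full = specs[-1]
        two_way = [t for t in full.fixed_terms if t.count(":") == 1]
        assert len(two_way) == 10

    def test_monotone_supersets(self):
        specs = build_model_sequence()
        for prev, cur in zip(specs, specs[1:]):
            assert set(prev.fixed_terms) <= set(cur.fixed_terms)

    def test_three_way_block(self):
        terms = build_model_sequence()[-1].fixed_terms
        assert "condition:group:timepoint" in terms
        assert "condition:group:hand" in terms
        assert "group:hand:sex" in terms
        assert "condition:group:hand:sex" not in terms

    def test_four_way_flag(self):
        terms = build_model_sequence(four_way=True)[-1].fixed_terms
        assert "condition:group:hand:sex" in terms

    def test_unknown_factor_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_model_sequence(["condition", "group", "hand", "sex", "age"])

    def test_hierarchy_enforced_in_spec(self):
        with pytest.raises(InvalidArgumentError):
            ModelSpec(fixed_terms=("condition", "condition:group"))


class TestFitMixedModel:
    def test_constant_response(self):
        obs = _obs(value=3.5)
        fit = fit_mixed_model(obs, ModelSpec())
        table = fit.coefficients.set_index("term")
        assert table.loc["Intercept", "beta"] == pytest.approx(3.5)
        assert fit.residual_sd ** 2 <= 1e-12

    def test_matches_ols_when_no_between_subject_variance(self):
        # residual-only data: mixed fit should collapse to OLS
        rng = np.random.default_rng(1)
        obs = _obs(n_subjects=30, seed=1)
        obs["value"] = 2.0 + 1.5 * (obs["condition"] == "role_differentiated") \
            + rng.normal(0, 0.5, len(obs))
        spec = ModelSpec(fixed_terms=("condition",))
        fit = fit_mixed_model(obs, spec)
        X = design_matrix(obs, spec).to_numpy()
        beta_ols = np.linalg.lstsq(X, obs["value"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(
            fit.coefficients["beta"].to_numpy(), beta_ols, atol=1e-4)
        assert fit.intercept_sd < 0.2

    def test_aic_identity(self):
        obs = _obs(n_subjects=20, seed=2)
        fit = fit_mixed_model(obs, ModelSpec(fixed_terms=("condition", "hand")))
        assert fit.aic == pytest.approx(
            2 * fit.n_params - 2 * fit.log_likelihood)
        assert fit.n_params == 3 + 2  # intercept + 2 terms + 2 variances

    def test_rank_deficiency_names_aliased_terms(self):
        obs = _obs(n_subjects=12, seed=3)
        obs["group"] = "CHI"  # no MCI level -> group column is all zero
        with pytest.raises(RankDeficiencyError) as err:
            fit_mixed_model(obs, ModelSpec(fixed_terms=("condition", "group")))
        assert "group" in err.value.aliased

    def test_needs_repeated_measures(self):
        obs = _obs(n_subjects=2, n_per_subject=1)
        with pytest.raises(InvalidArgumentError):
            fit_mixed_model(obs, ModelSpec())

    def test_containment_df_strata(self):
        obs = gen_observation_table(CohortConfig(
            counts={"CHI": (15, 8, 0, 0), "MCI": (10, 5, 0, 0)}, seed=4))
        fit = fit_mixed_model(obs, ModelSpec(
            fixed_terms=("condition", "group", "hand", "sex", "timepoint")))
        table = fit.coefficients.set_index("term")
        n_subj = obs["participant_id"].nunique()
        n_obs = len(obs)
        # between-participant terms: intercept, group, sex -> 3
        assert table.loc["group", "df"] == n_subj - 3
        assert table.loc["sex", "df"] == n_subj - 3
        # within-participant terms: condition, hand, timepoint -> 3
        assert table.loc["condition", "df"] == n_obs - n_subj - 3
        assert table.loc["group", "df"] < table.loc["condition", "df"]

    def test_parameter_recovery(self, recovery_cohort_cfg):
        import dataclasses

        from forcefluct.synthetic import DEFAULT_FIXED_EFFECTS

        terms = ("condition", "group", "hand", "sex", "timepoint",
                 "condition:group", "condition:hand")
        truth = DEFAULT_FIXED_EFFECTS
        nrep = 100
        cover = {t: 0 for t in ("Intercept",) + terms}
        for rep in range(nrep):
            cfg = dataclasses.replace(recovery_cohort_cfg, seed=1000 + rep)
            obs = gen_observation_table(cfg)
            fit = fit_mixed_model(obs, ModelSpec(fixed_terms=terms, reml=True))
            for _, row in fit.coefficients.iterrows():
                tv = (truth["intercept"] if row["term"] == "Intercept"
                      else truth[row["term"]])
                if abs(row["beta"] - tv) <= 2 * row["se"]:
                    cover[row["term"]] += 1
        for term, n_ok in cover.items():
            assert n_ok >= 90, f"{term}: {n_ok}/{nrep}"


class TestSelectBestModel:
    def test_minimum_aic(self):
        fits = [_fake_fit(aic=100), _fake_fit(aic=98), _fake_fit(aic=99)]
        assert select_best_model(fits) == 1

    def test_tie_goes_to_smaller_model(self):
        fits = [_fake_fit(aic=98, k=5), _fake_fit(aic=98, k=3)]
        assert select_best_model(fits) == 1

    def test_single_fit(self):
        assert select_best_model([_fake_fit(aic=50)]) == 0

    def test_empty_errors(self):
        with pytest.raises(InvalidArgumentError):
            select_best_model([])


def _fake_fit(aic=0.0, k=3, llf=0.0):
    return FitResult(spec=ModelSpec(), log_likelihood=llf, aic=aic,
                     n_params=k, coefficients=pd.DataFrame(),
                     intercept_sd=1.0, residual_sd=1.0, n_obs=10,
                     n_participants=5)


class TestLikelihoodRatioTest:
    def test_identical_fits(self):
        a = _fake_fit(llf=10.0)
        lr, p = likelihood_ratio_test(a, _fake_fit(llf=10.0), 1)
        assert lr == 0.0 and p == pytest.approx(1.0)

    def test_chi_square_example(self):
        lr, p = likelihood_ratio_test(_fake_fit(llf=10.0), _fake_fit(llf=12.0), 1)
        assert lr == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))
        assert p == pytest.approx(0.0455, abs=5e-4)

    def test_zero_df_rejected(self):
        with pytest.raises(InvalidArgumentError):
            likelihood_ratio_test(_fake_fit(llf=1.0), _fake_fit(llf=2.0), 0)

    def test_nesting_violation(self):
        with pytest.raises(NestingViolationError):
            likelihood_ratio_test(_fake_fit(llf=12.0), _fake_fit(llf=10.0), 1)


class TestEffectSizeR:
    @pytest.mark.parametrize("t,df,expected", [
        (5.13, 129, 0.41), (6.81, 128, 0.52), (-7.50, 129, 0.55),
        (2.33, 128, 0.20),
    ])
    def test_published_anchors(self, t, df, expected):
        assert round(effect_size_r(t, df), 2) == pytest.approx(expected)

    @pytest.mark.parametrize("t,df,expected", TABLE2_ROWS)
    def test_full_published_table(self, t, df, expected):
        assert round(effect_size_r(t, df), 2) == pytest.approx(expected, abs=0.005)

    def test_zero_t(self):
        assert effect_size_r(0.0, 100) == 0.0

    def test_invalid_df(self):
        with pytest.raises(InvalidArgumentError):
            effect_size_r(2.0, 0)

    @given(t1=st.floats(0.1, 50), t2=st.floats(0.1, 50),
           df=st.integers(1, 1000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_abs_t(self, t1, t2, df):
        lo, hi = sorted((t1, t2))
        assert effect_size_r(lo, df) <= effect_size_r(hi, df) + 1e-12

    @given(t=st.floats(0.1, 50), df1=st.integers(1, 500),
           df2=st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_df(self, t, df1, df2):
        lo, hi = sorted((df1, df2))
        assert effect_size_r(t, hi) <= effect_size_r(t, lo) + 1e-12

    def test_bounded(self):
        assert 0 <= effect_size_r(1e6, 1) < 1


class TestSummarizeContrasts:
    def test_intercept_only_single_row(self):
        fit = fit_mixed_model(_obs(seed=6), ModelSpec())
        rows = summarize_contrasts(fit)
        assert len(rows) == 1 and rows[0].term == "Intercept"

    def test_r_column_consistency(self):
        obs = _obs(n_subjects=16, seed=7)
        fit = fit_mixed_model(obs, ModelSpec(fixed_terms=("condition", "hand")))
        for row in summarize_contrasts(fit):
            assert row.r == pytest.approx(effect_size_r(row.t, row.df), abs=1e-9)

    def test_contrast_row_validates_r(self):
        with pytest.raises(InvalidArgumentError):
            ContrastRow(term="x", beta=1.0, se=0.5, df=100, t=2.0, p=0.05,
                        r=0.9)

    def test_term_labels(self):
        obs = _obs(n_subjects=16, seed=8)
        fit = fit_mixed_model(
            obs, ModelSpec(fixed_terms=("condition", "group", "condition:group")))
        frame = contrasts_frame(fit)
        assert "Condition (RD-BC)" in frame["term"].to_list()
        assert "Condition (RD-BC) x Group (MCI-CHI)" in frame["term"].to_list()


class TestStepwiseAnalysis:
    def test_trace_and_selection(self):
        obs = gen_observation_table(CohortConfig(
            counts={"CHI": (12, 6, 0, 0), "MCI": (10, 5, 0, 0)}, seed=11))
        result = stepwise_analysis(obs)
        fitted = [e for e in result["trace"] if "aic" in e]
        assert len(fitted) >= 2
        aics = [e["aic"] for e in fitted]
        assert min(aics) == pytest.approx(
            aics[[e["n_params"] for e in fitted].index(
                result["best_fit"].n_params)], rel=1e-6)
        assert not result["contrasts"].empty

    def test_aic_penalty_bounded_under_null(self):
        # adding null terms should not raise AIC by much more than 2 per df
        deltas = []
        for rep in range(10):
            null = {k: 0.0 for k in ("intercept", "condition")}
            null["intercept"] = 1.0
            obs = gen_observation_table(CohortConfig(
                counts={"CHI": (10, 5, 0, 0), "MCI": (8, 4, 0, 0)},
                fixed_effects=null, seed=300 + rep))
            base = fit_mixed_model(obs, ModelSpec())
            bigger = fit_mixed_model(obs, ModelSpec(fixed_terms=("condition",)))
            deltas.append(bigger.aic - base.aic)
        assert np.mean(deltas) < 2.5
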