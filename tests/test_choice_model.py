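"""Design matrix construction, IRLS logistic fit, nested LRTs, BIC ranking
and best-preferred-scenario synthesis."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sleepconjoint.choice_model import (
    DesignMatrix,
    TermSpec,
    best_scenario,
    bic_rank,
    build_design,
    canonical_interaction_pairs,
    encode_features,
    fit_logit,
    lrt_interaction,
    lrt_parameter,
)
from sleepconjoint.cohort import default_true_weights, simulate_random_choices
from sleepconjoint.scenario_space import Scenario


@pytest.fixture(scope="module")
def truth(space):
    return default_true_weights(space)


@pytest.fixture(scope="module")
def small_dataset(space, truth):
    return simulate_random_choices(space, truth, 3000, rng=101)


class TestEncodeFeatures:
    def test_all_reference_is_zero_vector(self, space):
        v, cols = encode_features(Scenario((1,) * 17), space)
        assert not v.any()
        assert len(v) == len(cols)

    def test_waso_level_three_sets_one_indicator(self, space):
        levels = [1] * 17
        levels[space.index_of("wake_after_sleep_onset")] = 3
        v, cols = encode_features(Scenario(tuple(levels)), space)
        waso_main = [
            i for i, c in enumerate(cols)
            if c.term == "main" and c.params == ("wake_after_sleep_onset",)
        ]
        assert len(waso_main) == 4
        assert v[waso_main].sum() == 1.0
        on = [i for i in waso_main if v[i] == 1.0]
        assert cols[on[0]].levels == (3,)

    def test_interaction_feature_is_indicator_product(self, space):
        levels = [1] * 17
        levels[space.index_of("wake_after_sleep_onset")] = 2
        levels[space.index_of("feeling_refreshed")] = 3
        v, cols = encode_features(Scenario(tuple(levels)), space)
        for i, c in enumerate(cols):
            if c.term != "pair":
                continue
            # brute-force product of the two indicator values
            expect = float(
                levels[space.index_of(c.params[0])] == c.levels[0]
                and levels[space.index_of(c.params[1])] == c.levels[1]
            )
            assert v[i] == expect


class TestDesignStructure:
    def test_canonical_pair_count(self):
        assert len(canonical_interaction_pairs()) == 28

    def test_column_bookkeeping(self, space, small_dataset):
        d = build_design(small_dataset, space)
        terms = pd.Series([c.term for c in d.columns]).value_counts()
        assert terms["main"] == 16 * 2 + 1 * 4 == 36
        assert terms["pair"] == 21 * 4 + 7 * 8 == 140
        assert terms["sleeper"] == 36
        assert terms["question"] == 36
        assert terms["intercept"] == 1
        assert d.X.shape == (3000, 249)

    def test_identical_scenarios_give_zero_scenario_columns(self, space):
        df = pd.DataFrame(
            {
                "participant_id": ["p"],
                "sleeper_group": ["good"],
                "chain_group": ["g"],
                "chain_id": ["c"],
                "trial_index": [1],
                "question_type": ["better"],
                **{f"a_{n}": [2] for n in space.names},
                **{f"b_{n}": [2] for n in space.names},
                "first_shown": ["a"],
                "chosen": ["a"],
                "judged_better": ["a"],
                "response_time_s": [30.0],
            }
        )
        d = build_design(df, space)
        scen = [i for i, c in enumerate(d.columns) if c.term != "intercept"]
        assert not d.X[0, scen].any()

    def test_ab_relabelling_is_a_no_op(self, space, small_dataset):
        # the design lives in the first-shown frame, so swapping the a/b
        # bookkeeping labels leaves X and y untouched
        df = small_dataset.copy()
        for n in space.names:
            df[[f"a_{n}", f"b_{n}"]] = df[[f"b_{n}", f"a_{n}"]].to_numpy()
        flip = {"a": "b", "b": "a"}
        for col in ("first_shown", "chosen", "judged_better"):
            df[col] = df[col].map(flip)
        d1 = build_design(small_dataset, space)
        d2 = build_design(df, space)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.y, d2.y)

    def test_presentation_order_flip_negates_intercept_only(self, space, truth):
        df = simulate_random_choices(space, truth, 6000, rng=33)
        d1 = build_design(df, space)
        f1 = fit_logit(d1)
        flipped = df.copy()
        flipped["first_shown"] = flipped["first_shown"].map({"a": "b", "b": "a"})
        d2 = build_design(flipped, space)
        f2 = fit_logit(d2)
        names = f1.names
        i0 = names.index("order_intercept")
        keep = [i for i in range(len(names)) if i != i0]
        np.testing.assert_allclose(f1.params[keep], f2.params[keep], atol=1e-6)
        assert f1.params[i0] == pytest.approx(-f2.params[i0], abs=1e-6)

    def test_missing_columns_rejected(self, space, small_dataset):
        with pytest.raises(ValueError, match="missing"):
            build_design(small_dataset.drop(columns=["judged_better"]), space)

    def test_bad_interaction_pair_rejected(self, space, small_dataset):
        spec = TermSpec(interaction_pairs=(("mood_day_before", "alertness"),))
        with pytest.raises(ValueError, match="crossing"):
            build_design(small_dataset, space, spec)


class TestFit:
    def test_matches_statsmodels_oracle(self, space, small_dataset):
        import statsmodels.api as sm

        spec = TermSpec(
            interaction_pairs=(), sleeper_interactions=False,
            question_interactions=False,
        )
        d = build_design(small_dataset, space, spec)
        ours = fit_logit(d)
        ref = sm.Logit(d.y, d.X).fit(disp=0, method="newton")
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-4)

    def test_null_data_coefficients_near_zero(self, space):
        rng = np.random.default_rng(55)
        pw = {p.name: (0.0,) * p.n_levels for p in space.parameters}
        null = default_true_weights(space)
        null = replace(null, part_worths=pw, interaction_weights={}, question_shifts={})
        df = simulate_random_choices(space, null, 10_000, rng=rng)
        spec = TermSpec(
            interaction_pairs=(), sleeper_interactions=False,
            question_interactions=False,
        )
        f = fit_logit(build_design(df, space, spec))
        z = np.abs(f.params / f.bse)
        assert (z < 4).all()
        assert (z < 3).mean() >= 0.95

    def test_deviance_identity_and_nesting(self, space, small_dataset):
        d = build_design(small_dataset, space)
        full = fit_logit(d)
        assert full.deviance == pytest.approx(-2 * full.llf)
        keep = [i for i, c in enumerate(d.columns) if c.term in ("main", "intercept")]
        restricted = fit_logit(d.subset(keep))
        assert full.deviance <= restricted.deviance + 1e-6

    def test_separation_flagged_and_ridged(self, space):
        # deterministic choices -> perfect separation on one feature
        n = 400
        rng = np.random.default_rng(2)
        rows = {
            "participant_id": ["p"] * n,
            "sleeper_group": ["good"] * n,
            "chain_group": ["g"] * n,
            "chain_id": ["c"] * n,
            "trial_index": np.arange(n),
            "question_type": ["better"] * n,
            "first_shown": ["a"] * n,
            "response_time_s": [30.0] * n,
        }
        for nme in ["a_" + x for x in default_true_weights().part_worths] + [
            "b_" + x for x in default_true_weights().part_worths
        ]:
            rows[nme] = rng.integers(1, 3, size=n)
        df = pd.DataFrame(rows)
        i = "total_sleep_time"
        better_a = df[f"a_{i}"] <= df[f"b_{i}"]
        df["judged_better"] = np.where(better_a, "a", "b")
        df["chosen"] = df["judged_better"]
        spec = TermSpec(interaction_pairs=(), sleeper_interactions=False,
                        question_interactions=False, main_only_params=(i,))
        f = fit_logit(build_design(df, space, spec))
        assert f.separation_warning
        assert np.isfinite(f.params).all()

    def test_empty_design_rejected(self, space, small_dataset):
        d = build_design(small_dataset, space)
        with pytest.raises(ValueError):
            fit_logit(d.subset([]))


class TestLRT:
    def test_waso_drop_width(self, space, small_dataset):
        d = build_design(small_dataset, space)
        drop = d.columns_for_parameter("wake_after_sleep_onset")
        # main 4 + pair 7x8 + sleeper 4 + question 4
        assert len(drop) == 4 + 56 + 4 + 4 == 68
        r = lrt_parameter(d, space, parameter="wake_after_sleep_onset")
        assert r.df == 68 and r.statistic >= 0

    def test_interaction_block_widths(self, space, small_dataset):
        d = build_design(small_dataset, space)
        r = lrt_interaction(d, space, pair=("wake_after_sleep_onset", "feeling_refreshed"))
        assert r.df == 4 * 2
        rq = lrt_interaction(d, space, pair=("feeling_refreshed", "question"))
        assert rq.df == 2

    def test_statistic_matches_independent_refits(self, space, truth):
        # oracle: fit both models from scratch (statsmodels, several starts)
        import statsmodels.api as sm

        df = simulate_random_choices(space, truth, 2000, rng=13)
        spec = TermSpec(interaction_pairs=(), sleeper_interactions=False,
                        question_interactions=False)
        d = build_design(df, space, spec)
        r = lrt_parameter(d, space, spec, parameter="total_sleep_time")
        keep = [i for i in range(d.X.shape[1])
                if i not in set(d.columns_for_parameter("total_sleep_time"))]
        llf_full = sm.Logit(d.y, d.X).fit(disp=0).llf
        llf_rest = sm.Logit(d.y, d.X[:, keep]).fit(disp=0).llf
        assert r.statistic == pytest.approx(2 * (llf_full - llf_rest), abs=1e-4)

    def test_dropping_nothing_gives_zero(self, space, small_dataset):
        from sleepconjoint.choice_model import _lrt_from_designs

        d = build_design(small_dataset, space)
        r = _lrt_from_designs(d, [], "nothing", alpha=0.01)
        assert r.statistic == 0.0 and r.df == 0

    def test_strong_interaction_detected(self, space, truth):
        boosted = replace(
            truth,
            interaction_weights={
                (("wake_after_sleep_onset", 5), ("feeling_refreshed", 3)): 1.0
            },
        )
        df = simulate_random_choices(space, boosted, 20_000, rng=21)
        d = build_design(df, space)
        f = fit_logit(d)
        r = lrt_interaction(
            d, space, pair=("wake_after_sleep_onset", "feeling_refreshed"),
            full_fit=f,
        )
        assert r.significant and r.p_value < 0.01

    def test_null_interaction_rejection_rate_near_alpha(self, space):
        # type-I calibration on a lean model (single candidate pair)
        pw = {p.name: (0.0,) * p.n_levels for p in space.parameters}
        pw["total_sleep_time"] = (0.0, -0.5, -1.0)
        null = default_true_weights(space)
        null = replace(null, part_worths=pw, interaction_weights={}, question_shifts={})
        spec = TermSpec(
            interaction_pairs=(("wake_after_sleep_onset", "feeling_refreshed"),),
            sleeper_interactions=False, question_interactions=False,
        )
        rng = np.random.default_rng(17)
        reps, rejections = 300, 0
        for _ in range(reps):
            df = simulate_random_choices(space, null, 2000, rng=rng)
            d = build_design(df, space, spec)
            f = fit_logit(d)
            r = lrt_interaction(
                d, space, spec,
                pair=("wake_after_sleep_onset", "feeling_refreshed"), full_fit=f,
            )
            rejections += r.significant
        from scipy.stats import binom

        assert binom.ppf(0.005, reps, 0.01) <= rejections <= binom.ppf(0.995, reps, 0.01)

    def test_unknown_parameter_rejected(self, space, small_dataset):
        d = build_design(small_dataset, space)
        with pytest.raises(KeyError):
            lrt_parameter(d, space, parameter="nonexistent")


class TestBIC:
    def test_bic_arithmetic(self, space, small_dataset):
        ranking = bic_rank(small_dataset, space, entities="parameters")
        n = len(small_dataset)
        for _, row in ranking.table.iterrows():
            assert row["bic"] == pytest.approx(
                -2 * row["llf"] + row["k"] * math.log(n)
            )
        # plausibility of the formula at printed magnitudes
        assert -2 * (-2822.0) + 3 * math.log(4176) == pytest.approx(5669.0, abs=0.5)

    def test_table_sorted_ascending(self, space, small_dataset):
        t = bic_rank(small_dataset, space).table
        assert (t["bic"].diff().dropna() >= 0).all()

    def test_largest_true_weight_ranks_first(self, space, truth):
        df = simulate_random_choices(space, truth, 8000, rng=30)
        ranking = bic_rank(df, space, entities="parameters")
        assert ranking.order[0] == "total_sleep_time"

    def test_zero_weight_entity_ranks_low(self, space, truth):
        df = simulate_random_choices(space, truth, 8000, rng=31)
        order = bic_rank(df, space).order
        # day_went_well has (near) zero truth; TST/mood carry the signal
        assert order.index("day_went_well") > order.index("total_sleep_time")
        assert order.index("day_went_well") > order.index("mood_day_after")

    def test_period_ranking_runs(self, space, small_dataset):
        t = bic_rank(small_dataset, space, entities="periods").table
        assert set(t["entity"]) == {
            "day_before", "pre_sleep", "during_sleep", "upon_waking", "day_after"
        }
        # during-sleep block has k = 2+4+2+2 main columns + intercept
        assert int(t.set_index("entity").loc["during_sleep", "k"]) == 11


class TestBestScenario:
    def _fit_with(self, space, coef_map):
        from sleepconjoint.choice_model import FitResult

        df = simulate_random_choices(space, default_true_weights(space), 50, rng=1)
        d = build_design(df, space)
        p = len(d.columns)
        params = np.zeros(p)
        for i, c in enumerate(d.columns):
            if c.term == "main":
                params[i] = coef_map.get((c.params[0], c.levels[0]), 0.0)
        return FitResult(
            params=params, bse=np.ones(p), cov=np.eye(p), llf=0.0, deviance=0.0,
            n_obs=50, columns=d.columns, converged=True,
            separation_warning=False, n_iter=0,
        )

    def test_all_zero_gives_reference_and_empty_mask(self, space):
        f = self._fit_with(space, {})
        best = best_scenario(f, [], space)
        assert best.scenario.levels == (1,) * 17
        assert not any(best.significant.values())

    def test_argmax_selects_highest_part_worth(self, space):
        f = self._fit_with(space, {("total_sleep_time", 2): -1.0,
                                   ("total_sleep_time", 3): -2.0})
        best = best_scenario(f, [], space)
        assert best.scenario.level_of("total_sleep_time", space) == 1
        assert "I think I slept for 9.5 hours" in best.narrative

    def test_tie_breaks_to_lower_level(self, space):
        f = self._fit_with(space, {("alertness", 2): 1.0, ("alertness", 3): 1.0})
        best = best_scenario(f, [], space)
        assert best.scenario.level_of("alertness", space) == 2

    def test_significant_parameters_highlighted(self, space, small_dataset):
        d = build_design(small_dataset, space)
        f = fit_logit(d)
        lrts = [lrt_parameter(d, space, parameter="total_sleep_time", full_fit=f)]
        best = best_scenario(f, lrts, space)
        if best.significant["total_sleep_time"]:
            phrase = space["total_sleep_time"].levels[
                best.scenario.level_of("total_sleep_time", space) - 1
            ]
            assert f"**{phrase}**" in best.narrative
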