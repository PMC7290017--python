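"""Bias statistics: inclusion, shift direction, proportions, chance levels,
the single-item sampling null, pull magnitude and memory consistency."""

import itertools

import numpy as np
import pytest

from ensemblepull import (
    ObserverDataset,
    ReferentialIntegrityError,
    UndefinedSummaryError,
    ValidationError,
    analytic_chance_restricted,
    ensemble_mean,
    estimate_pull_weight,
    exact_chance,
    include_trial,
    make_restricted_skeletons,
    memory_consistency,
    monte_carlo_chance,
    observer_bias,
    pull_magnitude,
    pull_model_chance,
    pull_percentage,
    shift_direction,
    single_item_null,
    trial_table,
)
from conftest import make_trial


def observer_from(part1, trial_specs):
    """trial_specs: list of (target, distractors, part2)."""
    obs = ObserverDataset("o", part1=dict(part1))
    obs.trials = [
        make_trial(i, t, d, r2) for i, (t, d, r2) in enumerate(trial_specs)
    ]
    return obs.validate()


class TestTrialPrimitives:
    @pytest.mark.parametrize(
        "ratings, expected",
        [((3, 4, 5), 4.0), ((-1, -1, -1), -1.0), ((1, 2, 5), 8 / 3)],
    )
    def test_ensemble_mean(self, ratings, expected):
        part1 = {"t": 3 if ratings[0] > 0 else -3}
        part1.update({f"d{k}": r for k, r in enumerate(ratings)})
        trial = make_trial(0, "t", ("d0", "d1", "d2"), part1["t"])
        assert ensemble_mean(trial, part1) == pytest.approx(expected)

    def test_ensemble_mean_excludes_target(self):
        part1 = {"t": -5, "d0": 3, "d1": 4, "d2": 5}
        trial = make_trial(0, "t", ("d0", "d1", "d2"), 1)
        assert ensemble_mean(trial, part1) == 4.0

    def test_missing_distractor_rating_raises(self):
        trial = make_trial(0, "t", ("d0", "d1", "d2"), 3)
        with pytest.raises(ReferentialIntegrityError):
            ensemble_mean(trial, {"t": 3, "d0": 3, "d1": 4})

    @pytest.mark.parametrize(
        "distractors, mode, included",
        [
            # r1=+3; m=(3+4+3)/3=10/3: |diff|=1/3 <= 0.5 -> excluded
            ((3, 4, 3), "full", False),
            # m=3.5 exactly: strict inequality -> excluded
            ((3, 4, 3.5), None, None),  # handled separately below
            ((4, 4, 5), "full", True),  # m=13/3, diff > 0.5
            ((4, 4, 5), "restricted", True),
        ],
    )
    def test_inclusion_rule(self, distractors, mode, included):
        if mode is None:
            return
        part1 = {"t": 3, "d0": distractors[0], "d1": distractors[1], "d2": distractors[2]}
        trial = make_trial(0, "t", ("d0", "d1", "d2"), 3)
        assert include_trial(trial, part1, mode) is included

    def test_inclusion_boundary_is_strict(self):
        # m - r1 = 0.5 exactly (distractors 3,3,4.5 impossible; use r1=2, m=2.5)
        part1 = {"t": 2, "d0": 2, "d1": 2, "d2": 3}  # m = 7/3, diff 1/3
        trial = make_trial(0, "t", ("d0", "d1", "d2"), 2)
        assert not include_trial(trial, part1, "full")
        part1b = {"t": 1, "d0": 1, "d1": 2, "d2": 2}  # m = 5/3; diff = 2/3 > 0.5
        trialb = make_trial(0, "t", ("d0", "d1", "d2"), 1)
        assert include_trial(trialb, part1b, "full")
        # a difference of exactly 0.5 (r1=+3, m=3.5) is excluded: the lone
        # skeleton trial fails inclusion, so no chance level is defined
        with pytest.raises(ValidationError):
            exact_chance([(3, 3.5)], "full")

    def test_restricted_requires_plus_minus_three(self):
        part1 = {"t": 4, "d0": 5, "d1": 5, "d2": 5}  # m=5, diff=1
        trial = make_trial(0, "t", ("d0", "d1", "d2"), 4)
        assert include_trial(trial, part1, "full")
        assert not include_trial(trial, part1, "restricted")

    @pytest.mark.parametrize(
        "r1, r2, m, expected",
        [
            (3, 4, 3.8, "toward"),
            (3, 3, 3.8, "none"),
            (-3, -2, -4.0, "away"),  # rating moved up, ensemble below
            (-3, -4, -4.0, "toward"),
            (3, 1, 4.0, "away"),
        ],
    )
    def test_shift_direction(self, r1, r2, m, expected):
        assert shift_direction(r1, r2, m) == expected


class TestObserverBias:
    def test_hand_built_fixture_three_of_five(self, toy_observer):
        """6 trials: 3 toward, 1 away, 1 none, 1 excluded -> 3/5."""
        summary = observer_bias(toy_observer, "full")
        assert (summary.n_included, summary.n_toward) == (5, 3)
        assert summary.proportion == pytest.approx(3 / 5)

    def test_matches_brute_force_enumeration(self, toy_observer):
        """Per-trial recount with independent primitive logic."""
        n_inc = n_toward = 0
        for trial in toy_observer.trials:
            r1 = toy_observer.part1[trial.target_id]
            m = sum(toy_observer.part1[d] for d in trial.distractor_ids) / 3
            if abs(m - r1) > 0.5:
                n_inc += 1
                r2 = trial.part2_rating
                if (r2 > r1 and m > r1) or (r2 < r1 and m < r1):
                    n_toward += 1
        summary = observer_bias(toy_observer, "full")
        assert (summary.n_included, summary.n_toward) == (n_inc, n_toward)

    def test_ten_included_seven_toward(self):
        part1 = {"t": 1, "d0": 3, "d1": 4, "d2": 5}
        specs = [("t", ("d0", "d1", "d2"), 2)] * 7 + [("t", ("d0", "d1", "d2"), 1)] * 3
        obs = observer_from(part1, specs)
        # 7 toward (r2=2 > r1=1 with m=4), 3 none
        assert observer_bias(obs, "full").proportion == pytest.approx(0.7)

    def test_all_trials_excluded_flags_observer(self):
        part1 = {"t": 3, "d0": 3, "d1": 3, "d2": 3}
        obs = observer_from(part1, [("t", ("d0", "d1", "d2"), 4)])
        with pytest.raises(UndefinedSummaryError):
            observer_bias(obs, "full")


class TestChanceLevels:
    def test_single_trial_above_exact_enumeration(self):
        # r1=+3, m=4.0: toward responses are {+4, +5} -> 2/10
        assert exact_chance([(3, 4.0)], "restricted").level == pytest.approx(0.2)

    def test_single_trial_below_exact_enumeration(self):
        # r1=+3, m=2.0: toward responses are {-5..-1, +1, +2} -> 7/10
        assert exact_chance([(3, 2.0)], "restricted").level == pytest.approx(0.7)

    def test_monte_carlo_converges_to_enumeration(self):
        skeletons = make_restricted_skeletons(20, seed=1)
        exact = exact_chance(skeletons, "restricted").level
        mc = monte_carlo_chance(skeletons, "restricted", n_sim=100_000, seed=2)
        assert mc.level == pytest.approx(exact, abs=0.005)

    def test_analytic_restricted_level(self):
        assert analytic_chance_restricted() == pytest.approx(0.45)
        assert analytic_chance_restricted(p_above=1.0) == pytest.approx(0.2)
        assert analytic_chance_restricted(p_above=0.0) == pytest.approx(0.7)

    def test_balanced_skeletons_hit_45_percent(self):
        skeletons = make_restricted_skeletons(40, seed=3)
        assert exact_chance(skeletons, "restricted").level == pytest.approx(0.45)
        mc = monte_carlo_chance(skeletons, "restricted", n_sim=20_000, seed=4)
        assert mc.level == pytest.approx(0.45, abs=0.01)

    def test_full_mode_uses_all_trials(self):
        # r1=+4 excluded from restricted but not from full
        skeletons = [(4, 5.0), (3, 4.0)]
        assert exact_chance(skeletons, "full").level == pytest.approx(
            (1 / 10 + 2 / 10) / 2
        )
        assert exact_chance(skeletons, "restricted").level == pytest.approx(0.2)

    def test_empty_skeleton_raises(self):
        with pytest.raises(ValidationError):
            monte_carlo_chance([], "restricted", seed=0)
        with pytest.raises(ValidationError):
            exact_chance([(3, 3.2)], "restricted")  # nothing passes inclusion

    def test_per_observer_designs_average(self):
        designs = [[(3, 4.0)], [(3, 2.0)]]
        assert exact_chance(designs, "restricted").level == pytest.approx(0.45)

    def test_pull_model_chance_closed_form(self):
        # w=0 responder crosses the 0.5 rounding boundary with prob Phi(-0.5/sigma)
        from scipy.stats import norm

        level = pull_model_chance(0.75).level
        assert level == pytest.approx(float(norm.sf(0.5 / 0.75)), abs=1e-12)
        # and via explicit snap-bin enumeration on balanced skeletons
        skeletons = make_restricted_skeletons(20, seed=5)
        via_bins = pull_model_chance(0.75, "restricted", skeletons).level
        assert via_bins == pytest.approx(level, abs=1e-9)

    def test_pull_model_chance_matches_simulation(self):
        from ensemblepull import simulate_restricted_proportions

        props = simulate_restricted_proportions(1, 2000, 50, 0.0, 0.75, seed=6)
        assert props.mean() == pytest.approx(pull_model_chance(0.75).level, abs=0.005)


class TestSingleItemNull:
    def test_degenerate_distractors_equal_observer_bias(self):
        part1 = {"t": 1, "d0": 3, "d1": 3, "d2": 3, "u": 2}
        specs = [
            ("t", ("d0", "d1", "d2"), 2),
            ("t", ("d0", "d1", "d2"), 1),
            ("u", ("d0", "d1", "d2"), 2),
        ]
        obs = observer_from(part1, specs)
        result = single_item_null(obs, n_iterations=50, seed=0)
        assert result.mean_proportion == pytest.approx(
            observer_bias(obs, "full").proportion
        )

    def test_deterministic_given_seed(self, toy_observer):
        a = single_item_null(toy_observer, n_iterations=1, seed=42)
        b = single_item_null(toy_observer, n_iterations=1, seed=42)
        assert a == b

    def test_matches_exhaustive_enumeration(self):
        """Two enumerable trials: exact average over all 3x3 item choices."""
        part1 = {"t": 2, "a": 1, "b": 4, "c": 5, "s": 3, "x": 1, "y": 2, "z": 5}
        obs = observer_from(
            part1, [("t", ("a", "b", "c"), 3), ("s", ("x", "y", "z"), 2)]
        )
        props = []
        for i, j in itertools.product(range(3), range(3)):
            singles = [part1[("a", "b", "c")[i]], part1[("x", "y", "z")[j]]]
            n_inc = n_toward = 0
            for (r1, r2), s in zip([(2, 3), (3, 2)], singles):
                if abs(s - r1) > 0.5:
                    n_inc += 1
                    if r2 != r1 and np.sign(r2 - r1) == np.sign(s - r1):
                        n_toward += 1
            if n_inc:
                props.append(n_toward / n_inc)
        expected = float(np.mean(props))
        result = single_item_null(obs, n_iterations=40_000, seed=1)
        assert result.mean_proportion == pytest.approx(expected, abs=0.01)

    def test_reuse_ensemble_inclusion_variant(self):
        part1 = {"t": 2, "a": 2, "b": 4, "c": 5}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 3)])
        # ensemble m = 11/3 -> included; the sampled item "a" (rating 2 = r1)
        # fails its own inclusion rule, so the default analysis drops those
        # iterations (leaving only toward items b, c), while the frozen
        # trial set keeps them as not-toward
        default = single_item_null(obs, n_iterations=3000, seed=2)
        frozen = single_item_null(
            obs, n_iterations=3000, seed=2, reuse_ensemble_inclusion=True
        )
        assert default.mean_proportion == pytest.approx(1.0)
        assert frozen.mean_proportion == pytest.approx(2 / 3, abs=0.03)


class TestPullMagnitude:
    def test_single_toward_trial(self):
        part1 = {"t": 3, "a": 5, "b": 5, "c": 5}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 4)])
        mag = pull_magnitude([obs], "full")
        assert mag.mean_available_diff == pytest.approx(2.0)
        assert mag.mean_shift == pytest.approx(1.0)
        assert mag.pct_of_max == pytest.approx(50.0)

    def test_full_pull_is_hundred_percent(self):
        part1 = {"t": 1, "a": 3, "b": 3, "c": 3}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 3)])
        assert pull_magnitude([obs], "full").pct_of_max == pytest.approx(100.0)

    def test_no_toward_trials_raises(self):
        part1 = {"t": 3, "a": 5, "b": 5, "c": 5}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 3)])
        with pytest.raises(UndefinedSummaryError):
            pull_magnitude([obs], "full")

    def test_printed_components_give_sixteen_percent(self):
        assert pull_percentage(0.61, 0.1) == pytest.approx(16.39, abs=0.01)


class TestMemoryConsistency:
    def test_unchanged_ratings_give_zero(self):
        part1 = {"t": 3, "a": 5, "b": 5, "c": 4}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 3)])
        assert memory_consistency([obs]) == 0.0

    def test_single_trial_shift_of_two(self):
        part1 = {"t": 3, "a": 5, "b": 5, "c": 4}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 5)])
        assert memory_consistency([obs]) == pytest.approx(2.0)

    def test_four_trials_mean_shift(self):
        part1 = {"t": 3, "a": 5, "b": 5, "c": 4}
        specs = [("t", ("a", "b", "c"), r2) for r2 in (3, 4, 4, 5)]
        obs = observer_from(part1, specs)  # shifts 0,1,1,2 -> mean 1.0
        assert memory_consistency([obs]) == pytest.approx(1.0)

    def test_no_inclusion_filter_applied(self):
        part1 = {"t": 3, "a": 3, "b": 3, "c": 3}  # trial would be excluded
        obs = observer_from(part1, [("t", ("a", "b", "c"), 5)])
        assert memory_consistency([obs]) == pytest.approx(2.0)


class TestPullWeightEstimator:
    def test_recovers_noise_free_pull_exactly(self):
        # r1=1, m=4, w yields raw 1+3w; with r2=2 the implied shift is 1
        part1 = {"t": 1, "a": 3, "b": 4, "c": 5}
        obs = observer_from(part1, [("t", ("a", "b", "c"), 2)])
        assert estimate_pull_weight([obs], "full") == pytest.approx(1 / 3)

    def test_trial_table_schema(self, toy_observer):
        table = trial_table(toy_observer, "full")
        assert list(table.columns) == [
            "trial_id", "r1", "r2", "m", "included", "direction"
        ]
        assert table["included"].sum() == 5
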