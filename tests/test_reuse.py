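import numpy as np
import pytest

from qreuse import (
    TARGET_PROGRAMS,
    canonical_arrays,
    detect_across_trial_reuse,
    exposure_effects,
    extract_template,
    make_trial_array,
    max_prior_similarity,
    parse,
    program_distance,
    rank_arrays_for_target,
    simulate_null,
    target_matching,
    template_diversity,
)
from qreuse.dataset import DatasetError
from qreuse.reuse import AcrossTrialModel


class TestReuseDetection:
    def test_same_template_counts_as_reuse(self, make_ds):
        ds = make_ds({"p1": ["(== (legs Blue) 2)", "(== (legs Red) 3)"]})
        assert detect_across_trial_reuse(ds) == {1: True}

    def test_different_functions_do_not(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"]})
        assert detect_across_trial_reuse(ds) == {1: False}

    def test_first_record_excluded_from_denominator(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(legs Blue)"], "p2": ["(legs Red)"]})
        flags = detect_across_trial_reuse(ds)
        assert 0 not in flags and 2 not in flags
        assert flags == {1: True}

    def test_reuse_searches_all_prior_trials(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)", "(legs Purple)"]})
        assert detect_across_trial_reuse(ds)[2] is True

    def test_agrees_with_zero_tree_edit_distance(self, make_ds, rng):
        """Cross-module oracle: reuse iff TED 0 against some prior question."""
        from qreuse.sampling import sample_program

        progs = [str(sample_program(rng=rng)) for _ in range(8)]
        ds = make_ds({"p1": progs})
        flags = detect_across_trial_reuse(ds)
        for i, rec in enumerate(ds.records):
            if i == 0:
                continue
            by_ted = any(
                program_distance(rec.program, ds.records[j].program) == 0 for j in range(i)
            )
            assert flags[i] == by_ted


class TestMaxPriorSimilarity:
    def test_single_prior(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"]})
        sims = max_prior_similarity(ds, norm_constant=1.0)
        assert sims == {1: 0.0}  # TED 1, norm 1

    def test_reused_records_are_excluded(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(legs Blue)"]})
        assert max_prior_similarity(ds) == {}

    def test_takes_the_maximum_over_priors(self, make_ds):
        ds = make_ds(
            {"p1": ["(shape Red)", "(+ (legs Blue) (legs Red))", "(legs Purple)"]}
        )
        sims = max_prior_similarity(ds, norm_constant=4.0)
        # (legs Purple): TED 1 to (shape Red), TED 2 to the sum -> max sim 0.75
        assert sims[2] == pytest.approx(0.75)


class TestTemplateDiversity:
    def test_all_distinct(self):
        assert template_diversity([parse("(legs Red)"), parse("(shape Red)")]) == 1.0

    def test_all_identical(self):
        assert template_diversity([parse("(legs Red)"), parse("(legs Blue)")]) == 0.0

    def test_two_of_three_shared(self):
        progs = [parse("(legs Red)"), parse("(legs Blue)"), parse("(shape Red)")]
        assert template_diversity(progs) == pytest.approx(1 / 3)


class TestSimulatedNull:
    def test_degenerate_pool_reproduces_observed_exactly(self, make_ds):
        """With one participant, each array's pool holds only that
        participant's own question, so every simulated dataset is the real
        one: null == observed, p = 1."""
        ds = make_ds({"p1": ["(legs Red)", "(legs Blue)", "(shape Red)"]})
        nd = simulate_null(ds, "reuse_rate", n_sims=50, rng=0)
        assert np.allclose(nd.null_values, nd.observed)
        assert nd.one_tailed_p == 1.0

    def test_single_sim_not_exceeding_observed_gives_p_one(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(legs Blue)"]})
        nd = simulate_null(ds, "reuse_rate", n_sims=1, rng=0)
        assert nd.one_tailed_p == 1.0  # (1+1)/(1+1)

    def test_recombination_null_excludes_current_template(self, make_ds):
        # pools contain both templates, so draws exist after exclusion
        ds = make_ds(
            {"p1": ["(legs Red)", "(shape Red)"], "p2": ["(shape Blue)", "(legs Blue)"]},
            array_cycle=["a0", "a1"],
        )
        nd = simulate_null(ds, "mean_recombination", n_sims=30, rng=0)
        assert 0.0 <= nd.observed <= 1.0
        assert nd.n_records == 2

    def test_empty_pool_after_exclusion_raises(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"]})
        # prior pool for a0 holds only (legs ...) questions; but the current
        # record's template differs, so exclusion empties nothing here — use
        # a dataset where prior pool only contains the current template
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"], "p2": ["(legs Blue)", "(legs Purple)"]})
        with pytest.raises(DatasetError):
            simulate_null(ds, "mean_recombination", n_sims=5, rng=0)

    def test_invalid_arguments(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"]})
        with pytest.raises(ValueError):
            simulate_null(ds, "reuse_rate", n_sims=0, rng=0)
        with pytest.raises(ValueError):
            simulate_null(ds, "unknown_statistic", rng=0)


class TestTargetMatching:
    def test_circle_variant_matches_square_head_count_target(self):
        circle = parse("(+ (map (lambda x0 (== (shape x0) Circle)) (set Blue Red Purple)))")
        assert target_matching(circle, "square_head_count") is True

    def test_combined_legs_target_has_no_free_parameters(self):
        exact = parse("(+ (map (lambda x0 (legs x0)) (set Blue Red Purple)))")
        assert target_matching(exact, "combined_legs") is True
        near = parse("(+ (legs Blue) (legs Red) (legs Purple))")
        assert target_matching(near, "combined_legs") is False

    def test_unrelated_question_does_not_match(self):
        assert target_matching(parse("(legs Red)"), "square_head_count") is False

    def test_unknown_target_id(self):
        with pytest.raises(KeyError):
            target_matching(parse("(legs Red)"), "nonexistent")


@pytest.fixture(scope="module")
def ranking():
    return rank_arrays_for_target(
        TARGET_PROGRAMS["square_head_count"], canonical_arrays(0).values()
    )


class TestRankArrays:
    def test_fully_revealed_heads_make_the_target_worthless(self, ranking):
        worst = ranking[ranking["trial_type"] == "worst"].iloc[0]
        assert worst["eig"] == 0.0

    def test_three_hidden_heads_give_1811_bits(self, ranking):
        # answer counts {0:1, 1:3, 2:3, 3:1}/8 -> H = 1.811 bits
        row = ranking[ranking["array_id"] == "h3l0"].iloc[0]
        assert row["eig"] == pytest.approx(1.811, abs=1e-3)

    def test_too_complex_when_a_single_query_ties_the_ceiling(self, ranking):
        """With one head hidden and no legs hidden, (shape X) matches the
        counting target's EIG with far fewer functions."""
        row = ranking[ranking["array_id"] == "h1l0"].iloc[0]
        assert bool(row["too_complex"]) is True
        assert row["trial_type"] == "too_complex"

    def test_best_is_highest_eig_unflagged(self, ranking):
        best = ranking[ranking["trial_type"] == "best"].iloc[0]
        assert best["eig"] == ranking["eig"].max()
        assert not best["too_complex"]

    def test_all_four_trial_types_assigned_for_both_targets(self):
        for target in TARGET_PROGRAMS.values():
            ranking = rank_arrays_for_target(target, canonical_arrays(0).values())
            assert set(ranking["trial_type"].dropna()) == {"best", "medium", "worst", "too_complex"}


class TestExposureEffects:
    def test_requires_condition_labels(self, make_ds):
        ds = make_ds({"p1": ["(legs Red)", "(shape Red)"]})
        with pytest.raises(DatasetError):
            exposure_effects(ds)

    def test_identically_generated_conditions_center_on_zero(self):
        """With rho=0 and kappa=0 the agent ignores memory entirely, so the
        exposure and no-exposure cells are exchangeable and the reuse-effect
        CI covers zero."""
        from qreuse.simulate import AgentParams, StudyDesign, generate_dataset

        ds = generate_dataset(
            AgentParams(rho_reuse=0.0, kappa_recombine=0.0, seed=11),
            StudyDesign.study2(n_per_cell=20, assignment_seed=12),
        )
        effects = exposure_effects(ds, measure="text", n_boot=300, rng=13)
        reuse = next(e for e in effects if e.name == "reuse_effect")
        assert reuse.ci_low <= 0.0 <= reuse.ci_high

    def test_model_results_summary(self, make_ds):
        from qreuse.simulate import AgentParams, StudyDesign, generate_dataset
        from qreuse.reuse import ExposureModel

        ds = generate_dataset(
            AgentParams(rho_reuse=0.4, seed=5), StudyDesign.study2(n_per_cell=10, assignment_seed=5)
        )
        res = ExposureModel(ds, measure="text").fit(n_boot=100, rng=0)
        assert "reuse_effect" in res.summary()
        assert res.reuse_effect.n_exposure == 40
        json_blob = res.to_json()
        assert {e["name"] for e in json_blob["effects"]} == {
            "reuse_effect", "recombination_effect_text"
        }


class TestAcrossTrialModel:
    def test_fit_reports_consistent_statistics(self, make_ds):
        ds = make_ds(
            {
                "p1": ["(legs Red)", "(legs Blue)", "(shape Red)"],
                "p2": ["(shape Blue)", "(legs Purple)", "(shape Purple)"],
            },
            array_cycle=["a0", "a1", "a2"],
        )
        res = AcrossTrialModel(ds).fit(n_sims=50, rng=0)
        flags = detect_across_trial_reuse(ds)
        assert res.reuse_rate == pytest.approx(np.mean(list(flags.values())))
        assert 0 < res.reuse.one_tailed_p <= 1
        assert "reuse rate" in res.summary()
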