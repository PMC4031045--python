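"""Group statistics: exclusion, curves, correlations, splits, strata."""

import numpy as np
import pytest
from scipy import stats

from optiprior.analysis import (
    correlate_trait_prior,
    empirical_accuracy,
    exclude_low_performers,
    fisher_z_compare,
    optimist_mask,
    performance_curve,
    split_group_tests,
    under_over_observed_analysis,
)
from optiprior.bayes import BayesParams
from optiprior.cohort import CohortConfig, generate_cohort, simulate_subject
from optiprior.fitting import fit_cohort
from optiprior.task import TaskConfig, generate_schedule


def make_agent_subject(gamma, seed, n_fractals=60, trait=None, prior_mean=0.5):
    rng = np.random.default_rng(seed)
    sch = generate_schedule(TaskConfig(n_fractals=n_fractals), rng)
    p = BayesParams(prior_mean * 2, (1 - prior_mean) * 2, gamma)
    return simulate_subject(p, sch, "bayes", rng, subject_id=f"a{seed}", trait_score=trait)


class TestExclusion:
    def test_maximizer_never_excluded(self):
        subj = make_agent_subject(gamma=500.0, seed=0)
        acc, n = empirical_accuracy(subj)
        assert acc > 0.9
        res = exclude_low_performers([subj])
        assert res.kept == [subj] and not res.excluded

    def test_random_agent_excluded_about_half_the_time(self):
        """A gamma=0 agent is a fair coin on ~60 scored decisions, so the
        <=50% rule catches it with the binomial(60, .5) mass at <= n/2."""
        flags = []
        for seed in range(40):
            subj = make_agent_subject(gamma=0.0, seed=seed)
            res = exclude_low_performers([subj])
            flags.append(len(res.excluded) == 1)
        # P(Binom(n,1/2) <= n/2) is ~0.54 at n=60; allow generous MC slack
        assert 0.3 < np.mean(flags) < 0.8

    def test_exclusion_count_matches_hand_count(self):
        cohort = [make_agent_subject(500.0, s) for s in range(3)] + [
            make_agent_subject(0.0, s) for s in range(3, 6)
        ]
        res = exclude_low_performers(cohort)
        hand = sum(1 for s in cohort if empirical_accuracy(s)[0] <= 0.5)
        assert len(res.excluded) == hand
        assert len(res.kept) + len(res.excluded) == 6


class TestPerformanceCurve:
    def test_maximizer_curve_is_step_like(self):
        subjects = [make_agent_subject(500.0, s) for s in range(6)]
        curve = performance_curve(subjects, bin_width=0.2)
        mids = (curve.bin_edges[:-1] + curve.bin_edges[1:]) / 2
        left = curve.fraction_chose_fractal[(mids < -0.15) & (curve.counts > 0)]
        right = curve.fraction_chose_fractal[(mids > 0.15) & (curve.counts > 0)]
        assert np.nanmean(left) < 0.15
        assert np.nanmean(right) > 0.85

    def test_all_fractal_choosers_curve_is_one(self, small_schedule):
        from optiprior.task import SubjectData

        subj = SubjectData(
            subject_id="x",
            schedule=small_schedule,
            choices=["fractal"] * small_schedule.n_decisions,
        )
        curve = performance_curve([subj])
        assert np.all(curve.fraction_chose_fractal[curve.counts > 0] == 1.0)
        assert np.all(np.isnan(curve.fraction_chose_fractal[curve.counts == 0]))

    def test_optimists_above_pessimists_for_negative_delta(self):
        """Optimistic priors inflate fractal choices exactly where the observed
        rate falls short of the square's probability."""
        opt = [make_agent_subject(8.0, s, prior_mean=0.8) for s in range(8)]
        pes = [make_agent_subject(8.0, 100 + s, prior_mean=0.2) for s in range(8)]
        c_opt = performance_curve(opt, group_label="optimist")
        c_pes = performance_curve(pes, group_label="pessimist")
        mids = (c_opt.bin_edges[:-1] + c_opt.bin_edges[1:]) / 2
        neg = (mids < 0) & (c_opt.counts > 5) & (c_pes.counts > 5)
        assert np.nanmean(c_opt.fraction_chose_fractal[neg]) > np.nanmean(
            c_pes.fraction_chose_fractal[neg]
        )


class TestCorrelations:
    def test_perfect_linear_pair(self):
        x = np.arange(10.0)
        res = correlate_trait_prior(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_p_value_matches_t_transform_oracle(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 30))
        res = correlate_trait_prior(x, y)
        t = res.r * np.sqrt((30 - 2) / (1 - res.r**2))
        p_oracle = 2 * stats.t.sf(abs(t), 30 - 2)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)

    def test_bonferroni_worked_example(self):
        # raw p of 0.001 survives the 42-comparison family at 0.042
        x = np.arange(20.0)
        res = correlate_trait_prior(x, x)
        assert res.p_adjusted == min(1.0, 42 * res.p)
        assert min(1.0, 42 * 0.001) == pytest.approx(0.042)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_trait_prior([1, 1, 1, 1], [1, 2, 3, 4])

    def test_planted_cohort_recovers_positive_correlation(self):
        cohort = generate_cohort(CohortConfig(rng_seed=8))
        # correlate trait against the *generating* prior means: the planted
        # effect must be visible before any fitting enters the pipeline
        res = correlate_trait_prior(
            [s.trait_score for s in cohort],
            [s.true_params["prior_mean"] for s in cohort],
        )
        assert res.r > 0 and res.p < 0.05


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.3, 40, 0.3, 60)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_published_comparison_value(self):
        # the reward vs reduced-uncertainty contrast: r=.438 (n=51) vs .009 (n=51)
        z, p = fisher_z_compare(0.438, 51, 0.009, 51)
        assert z == pytest.approx(2.26, abs=0.01)
        assert p == pytest.approx(0.024, abs=0.003)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.5, 30, 0.1, 50)
        z2, p2 = fisher_z_compare(0.1, 50, 0.5, 30)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.2, 50)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.2, 50)


class TestGroupSplit:
    def test_tie_scores_assigned_to_pessimists(self):
        scores = [10, 10, 20]  # mean = 40/3; 10 <= mean -> pessimist
        mask = optimist_mask(scores)
        assert mask.tolist() == [False, False, True]
        scores = [10, 20, 15]  # 15 equals the mean exactly -> pessimist
        assert optimist_mask(scores).tolist() == [False, True, False]

    def test_planted_cohort_prior_mean_differs_gamma_does_not(self):
        """The exp1-style planted effect shows up in the fitted prior mean but
        not in the softmax steepness, mirroring the optimist/pessimist table."""
        cohort = generate_cohort(CohortConfig(trait_prior_corr=0.8, rng_seed=14))
        fits = fit_cohort("bayes_full", cohort, n_starts=10, rng=0)
        res = split_group_tests(cohort, fits)
        assert res.n_optimists + res.n_pessimists == len(cohort)
        assert res.table.loc["prior_mean", "p"] < 0.05
        assert (
            res.table.loc["prior_mean", "optimist_mean"]
            > res.table.loc["prior_mean", "pessimist_mean"]
        )
        assert res.table.loc["gamma", "p"] > 0.05

    def test_identical_groups_are_null(self, bayes_subject):
        from optiprior.fitting import fit_subject
        import dataclasses

        fit = fit_subject("bayes_full", bayes_subject, n_starts=4, rng=0)
        cohort, fits = [], []
        for i, trait in enumerate([5, 5, 20, 20]):
            cohort.append(dataclasses.replace(bayes_subject))
            cohort[-1].trait_score = trait
            fits.append(fit)
        res = split_group_tests(cohort, fits)
        assert res.table.loc["prior_mean", "p"] == pytest.approx(1.0)


class TestUnderOver:
    def test_threshold_decisions_belong_to_neither_stratum(self):
        cohort = generate_cohort(CohortConfig(n_subjects=6, rng_seed=5))
        res = under_over_observed_analysis(cohort, threshold=4)
        from optiprior.task import summarize_decisions

        for subj, row in zip(cohort, res.per_subject.itertuples()):
            summaries = summarize_decisions(subj.schedule)
            n_under = sum(s.n_shown < 4 for s in summaries)
            n_over = sum(s.n_shown > 4 for s in summaries)
            n_at = sum(s.n_shown == 4 for s in summaries)
            assert n_under + n_over + n_at == 60
            if n_under == 0:
                assert np.isnan(row.under_bias)

    def test_null_cohort_both_strata_nonsignificant(self):
        ps = []
        for rep in range(5):
            cohort = generate_cohort(
                CohortConfig(trait_prior_corr=0.0, rng_seed=600 + rep)
            )
            res = under_over_observed_analysis(cohort)
            ps.extend([res.p_under, res.p_over])
        # with no planted effect, p-values should not pile up near zero
        assert np.mean(np.array(ps) < 0.05) < 0.3

    def test_strong_effect_concentrates_in_under_stratum(self):
        """With a strongly planted prior effect the optimist-pessimist gap is
        wider for sparsely observed fractals than for well observed ones."""
        gaps_under, gaps_over = [], []
        for rep in range(6):
            cohort = generate_cohort(
                CohortConfig(trait_prior_corr=0.9, rng_seed=700 + rep)
            )
            res = under_over_observed_analysis(cohort)
            ps = res.per_subject.dropna()
            gaps_under.append(
                ps[ps.optimist].under_bias.mean() - ps[~ps.optimist].under_bias.mean()
            )
            gaps_over.append(
                ps[ps.optimist].over_bias.mean() - ps[~ps.optimist].over_bias.mean()
            )
        assert np.mean(gaps_under) > np.mean(gaps_over)
        assert np.mean(gaps_under) > 0
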