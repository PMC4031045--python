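"""Bayesian observer: prior density, posterior mean, softmax, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optiprior.bayes import (
    BayesParams,
    FractalEvidence,
    choice_prob,
    log_likelihood,
    posterior_mean,
    prior_density,
)
from optiprior.task import (
    DecisionEvent,
    ObservationEvent,
    SubjectData,
    TrialSchedule,
)


def quadrature_posterior_mean(alpha, beta, n, N):
    """Oracle: posterior mean by adaptive quadrature of prior x likelihood."""
    from scipy.integrate import quad

    def unnorm(c):
        return np.exp((alpha - 1 + n) * np.log(c) + (beta - 1 + N - n) * np.log1p(-c))

    num, _ = quad(lambda c: c * unnorm(c), 0.0, 1.0, epsabs=0, epsrel=1e-11, limit=300)
    den, _ = quad(unnorm, 0.0, 1.0, epsabs=0, epsrel=1e-11, limit=300)
    return num / den


def make_subject(decisions, valence="reward"):
    """Subject with prescribed (outcomes, b, choice) per decision, one fractal each."""
    events, choices, probs = [], [], {}
    for fid, (outcomes, b, choice) in enumerate(decisions):
        probs[fid] = 0.5
        for r in outcomes:
            events.append(ObservationEvent(fid, r))
        events.append(DecisionEvent(fid, b))
        choices.append(choice)
    sch = TrialSchedule(events=tuple(events), fractal_probs=probs, valence=valence)
    return SubjectData(subject_id="t", schedule=sch, choices=choices)


class TestPriorDensity:
    def test_uniform_prior_is_flat(self):
        p = BayesParams(1.0, 1.0, 1.0)
        c = np.linspace(0.05, 0.95, 9)
        assert np.allclose(prior_density(c, p), 1.0)

    def test_jeffreys_density_at_half(self):
        # Beta(1/2, 1/2) density at 0.5 is 2/pi
        p = BayesParams(0.5, 0.5, 1.0)
        assert prior_density(0.5, p) == pytest.approx(2 / np.pi, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_density_integrates_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = BayesParams(rng.uniform(0.3, 5), rng.uniform(0.3, 5), 1.0)
        c = np.linspace(1e-6, 1 - 1e-6, 200_001)
        assert np.trapezoid(prior_density(c, p), c) == pytest.approx(1.0, abs=1e-3)


class TestPosteriorMean:
    def test_no_data_returns_prior_mean(self):
        p = BayesParams(0.5, 0.5, 1.0)
        assert posterior_mean(p, FractalEvidence(0, 0)) == 0.5

    def test_symmetric_evidence_preserves_symmetric_prior(self):
        p = BayesParams(0.5, 0.5, 1.0)
        assert posterior_mean(p, FractalEvidence(2, 4)) == 0.5

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a, b = rng.uniform(0.1, 10, 2)
            N = int(rng.integers(0, 30))
            n = int(rng.integers(0, N + 1))
            got = posterior_mean(BayesParams(a, b, 1.0), FractalEvidence(n, N))
            assert got == pytest.approx(quadrature_posterior_mean(a, b, n, N), abs=1e-6)

    def test_prior_influence_washes_out(self):
        """With empirical rate fixed, the posterior mean converges to it."""
        p = BayesParams(8.0, 2.0, 1.0)  # strongly optimistic prior
        rate = 0.25
        prev_gap = None
        for N in (4, 40, 400, 4000):
            n = int(N * rate)
            gap = abs(posterior_mean(p, FractalEvidence(n, N)) - rate)
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert gap < 0.01

    def test_invalid_evidence_rejected(self):
        with pytest.raises(ValueError):
            FractalEvidence(5, 4)


class TestChoiceProb:
    def test_equal_estimates_give_coin_flip(self):
        for gamma in (0.0, 1.0, 50.0):
            assert choice_prob(0.3, 0.3, gamma) == pytest.approx(0.5)

    def test_zero_steepness_is_random(self):
        assert choice_prob(0.9, 0.1, 0.0) == pytest.approx(0.5)

    def test_large_steepness_maximizes(self):
        assert choice_prob(0.7, 0.5, 1000.0) > 0.999

    def test_punishment_flips_preference(self):
        # higher estimated punishment probability -> avoid the fractal
        assert choice_prob(0.7, 0.5, 10.0, valence="punishment") < 0.5

    @given(
        c=st.floats(0, 1),
        b=st.floats(0, 1),
        g=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_complementarity(self, c, b, g):
        assert choice_prob(c, b, g) + choice_prob(b, c, g) == pytest.approx(1.0)


class TestLogLikelihood:
    def test_zero_gamma_is_chance(self, bayes_subject):
        p = BayesParams(2.0, 1.0, 0.0)
        expected = bayes_subject.n_decisions * np.log(0.5)
        assert log_likelihood(p, bayes_subject) == pytest.approx(expected)

    def test_single_decision_closed_form(self):
        # evidence 7/10 with uniform prior-ish shapes tuned so c_hat = 0.7
        subj = make_subject([(([1] * 7 + [0] * 3), 0.5, "fractal")])
        p = BayesParams(0.5, 0.5, 10.0)
        c_hat = (0.5 + 7) / (1 + 10)
        expected = -np.log1p(np.exp(-10.0 * (c_hat - 0.5)))
        assert log_likelihood(p, subj) == pytest.approx(expected, rel=1e-12)

    def test_observation_order_irrelevant(self):
        a = make_subject([((1, 1, 0, 0), 0.4, "fractal")])
        b = make_subject([((0, 1, 0, 1), 0.4, "fractal")])
        p = BayesParams(1.7, 0.6, 5.0)
        assert log_likelihood(p, a) == log_likelihood(p, b)

    def test_prior_only_decision_allowed(self):
        subj = make_subject([((), 0.4, "fractal")])
        p = BayesParams(2.0, 1.0, 3.0)
        expected = np.log(choice_prob(2 / 3, 0.4, 3.0))
        assert log_likelihood(p, subj) == pytest.approx(expected)

    def test_punishment_valence_scores_avoidance(self):
        # fractal punished every time; avoiding it must be the likely choice
        subj = make_subject([((1, 1, 1, 1), 0.5, "square")], valence="punishment")
        p = BayesParams(1.0, 1.0, 10.0)
        assert log_likelihood(p, subj) > np.log(0.5)

    def test_continuous_in_parameters(self, bayes_subject):
        base = BayesParams(1.0, 1.0, 5.0)
        ll0 = log_likelihood(base, bayes_subject)
        for eps in (1e-5, 1e-6):
            ll = log_likelihood(BayesParams(1.0 + eps, 1.0, 5.0), bayes_subject)
            assert abs(ll - ll0) < 1e-2
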