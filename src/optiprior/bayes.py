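"""Bayesian observer: Beta prior over outcome probability, softmax choice.

The observer holds a Beta(alpha, beta) prior over each fractal's hidden
outcome probability.  After observing ``n`` outcomes in ``N`` presentations
the posterior is Beta(alpha + n, beta + N - n), and decisions are driven by
its mean

    c_hat = (alpha + n) / (alpha + beta + N),

so the prior acts like ``alpha + beta`` pseudo-observations whose influence
washes out as real evidence accumulates.  Choices follow a logistic softmax
on the difference between ``c_hat`` and the square's stated probability, with
steepness ``gamma`` (0 = random, large = maximizing).  In the punishment
variant the sign is flipped: subjects avoid the option with the higher
estimated punishment probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_expit
from scipy.stats import beta as beta_dist
from scipy.special import expit

from .task import SubjectData, summarize_decisions

__all__ = [
    "BayesParams",
    "FractalEvidence",
    "prior_density",
    "posterior_mean",
    "choice_prob",
    "log_likelihood",
]

GAMMA_MAX = 100.0  # softmax steepness cap, keeps exp() well-conditioned


@dataclass(frozen=True)
class BayesParams:
    """Beta-prior shapes and softmax steepness."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.gamma < 0:
            raise ValueError("softmax steepness must be non-negative")

    @property
    def prior_mean(self) -> float:
        """Expected outcome probability before any observation, alpha/(alpha+beta)."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class FractalEvidence:
    """Sufficient statistics of one fractal's observation history."""

    n_rewards: int
    n_shown: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_rewards <= self.n_shown:
            raise ValueError("need 0 <= n_rewards <= n_shown")


def prior_density(c, params: BayesParams):
    """Beta(alpha, beta) prior density at probability ``c``."""
    return beta_dist.pdf(c, params.alpha, params.beta)


def posterior_mean(params: BayesParams, ev: FractalEvidence) -> float:
    """Posterior-mean estimate of the outcome probability after the evidence."""
    return (params.alpha + ev.n_rewards) / (
        params.alpha + params.beta + ev.n_shown
    )


def choice_prob(c_hat, b, gamma, valence: str = "reward"):
    """Probability of choosing the fractal over the square.

    Logistic softmax of the estimate difference: expit(gamma * (c_hat - b))
    for reward seeking, sign flipped for punishment avoidance.  Accepts
    scalars or arrays.
    """
    sign = 1.0 if valence == "reward" else -1.0
    return expit(sign * gamma * (np.asarray(c_hat, dtype=float) - b))


def _decision_arrays(data: SubjectData):
    """Vectorized per-decision evidence (n, N, b) and the choice indicator."""
    summaries = summarize_decisions(data.schedule)
    n = np.array([s.n_rewards for s in summaries], dtype=float)
    N = np.array([s.n_shown for s in summaries], dtype=float)
    b = np.array([s.square_prob for s in summaries], dtype=float)
    chose_fractal = np.array(
        [c == "fractal" for c in data.choices], dtype=bool
    )
    return n, N, b, chose_fractal


def log_likelihood(params: BayesParams, data: SubjectData) -> float:
    """Log-likelihood of the recorded choices under the Bayesian observer.

    Evidence for each decision is the prefix of observation screens preceding
    it; a never-observed fractal is scored from the prior alone.
    """
    n, N, b, chose_fractal = _decision_arrays(data)
    c_hat = (params.alpha + n) / (params.alpha + params.beta + N)
    sign = 1.0 if data.schedule.valence == "reward" else -1.0
    z = sign * params.gamma * (c_hat - b)
    # log p(choice): log_expit(z) if fractal chosen, log_expit(-z) otherwise
    return float(np.sum(log_expit(np.where(chose_fractal, z, -z))))
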