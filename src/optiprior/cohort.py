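"""Synthetic subject cohorts with a planted trait-optimism effect.

Each simulated subject gets a trait-optimism score (an integer on the 0-24
LOT-R scale) and generating model parameters, with the trait score and the
Beta-prior mean drawn from a bivariate Gaussian so a configurable correlation
is planted between them.  Marginal moments default to the reward-seeking
study conditions: trait 14.7 (SD 4.42), prior mean 0.42 (SD 0.23), softmax
steepness 7.88 (SD 3.93), trait-prior correlation 0.44, 51 subjects.  Every
subject receives a freshly randomized schedule for the chosen design and
their choices are simulated from the generating agent.

Designs:

* ``exp1`` — interleaved groups of 5, mean 4 observations per fractal, reward;
* ``exp2`` — blocked, mean 10 observations per fractal, reward (the
  reduced-uncertainty control);
* ``exp3`` — as exp1 but punishment avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .task import (
    DecisionEvent,
    ObservationEvent,
    SubjectData,
    TaskConfig,
    TrialSchedule,
    generate_schedule,
)
from .bayes import BayesParams
from . import rl as _rl

__all__ = [
    "CohortConfig",
    "design_config",
    "draw_subject_params",
    "simulate_subject",
    "generate_cohort",
]

TRAIT_RANGE = (0, 24)
PRIOR_MEAN_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class CohortConfig:
    """Population moments and design for one synthetic cohort."""

    n_subjects: int = 51
    trait_mean: float = 14.7
    trait_sd: float = 4.42
    prior_mean_mean: float = 0.42
    prior_mean_sd: float = 0.23
    trait_prior_corr: float = 0.44
    concentration: float = 2.0  # alpha + beta; pseudo-observation count of the prior
    gamma_mean: float = 7.88
    gamma_sd: float = 3.93
    agent_type: str = "bayes"
    design: str = "exp1"
    rng_seed: Union[int, None] = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if min(self.trait_sd, self.prior_mean_sd, self.gamma_sd) <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 < self.trait_prior_corr < 1.0:
            raise ValueError("trait_prior_corr must lie strictly in (-1, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.agent_type not in ("bayes", "rl"):
            raise ValueError("agent_type must be 'bayes' or 'rl'")
        if self.design not in ("exp1", "exp2", "exp3"):
            raise ValueError("design must be exp1, exp2 or exp3")


def design_config(design: str) -> TaskConfig:
    """Task configuration for one of the three experimental designs."""
    if design == "exp1":
        return TaskConfig(mean_presentations=4.0, interleaving="interleaved_groups_of_5")
    if design == "exp2":
        return TaskConfig(mean_presentations=10.0, interleaving="blocked")
    if design == "exp3":
        return TaskConfig(
            mean_presentations=4.0,
            interleaving="interleaved_groups_of_5",
            valence="punishment",
        )
    raise ValueError("design must be exp1, exp2 or exp3")


def draw_subject_params(
    config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-subject generating parameters with the planted correlation.

    (trait, prior mean) come from a bivariate Gaussian with the configured
    marginal moments and correlation; traits are then rounded to integers and
    clipped to the questionnaire range, prior means clipped away from {0, 1}.
    The planted correlation refers to the pre-rounding, pre-clipping values,
    which are kept in the ``trait_raw`` / ``prior_mean_raw`` columns.  The
    Beta shapes follow from the prior mean and the shared concentration
    alpha + beta; softmax steepness gamma is truncated-normal positive.
    """
    rho = config.trait_prior_corr
    cov = np.array(
        [
            [config.trait_sd**2, rho * config.trait_sd * config.prior_mean_sd],
            [rho * config.trait_sd * config.prior_mean_sd, config.prior_mean_sd**2],
        ]
    )
    mean = np.array([config.trait_mean, config.prior_mean_mean])
    draws = rng.multivariate_normal(mean, cov, size=config.n_subjects)
    trait_raw, prior_raw = draws[:, 0], draws[:, 1]

    trait = np.clip(np.rint(trait_raw), *TRAIT_RANGE).astype(int)
    prior_mean = np.clip(prior_raw, *PRIOR_MEAN_CLIP)
    alpha = prior_mean * config.concentration
    beta = (1.0 - prior_mean) * config.concentration

    a = (0.0 - config.gamma_mean) / config.gamma_sd  # truncate at gamma > 0
    gamma = truncnorm.rvs(
        a, np.inf, loc=config.gamma_mean, scale=config.gamma_sd,
        size=config.n_subjects, random_state=rng,
    )

    return pd.DataFrame(
        {
            "trait_score": trait,
            "trait_raw": trait_raw,
            "prior_mean_raw": prior_raw,
            "prior_mean": prior_mean,
            "alpha": alpha,
            "beta": beta,
            "gamma": gamma,
        }
    )


def _bayes_choice_draws(
    params: BayesParams, schedule: TrialSchedule, rng: np.random.Generator
) -> list:
    from .bayes import choice_prob, posterior_mean, FractalEvidence

    counts: dict = {}
    choices = []
    for ev in schedule.events:
        if isinstance(ev, ObservationEvent):
            n, N = counts.get(ev.fractal_id, (0, 0))
            counts[ev.fractal_id] = (n + int(ev.outcome), N + 1)
        else:
            n, N = counts.get(ev.fractal_id, (0, 0))
            c_hat = posterior_mean(params, FractalEvidence(n, N))
            p = choice_prob(c_hat, ev.square_prob, params.gamma, schedule.valence)
            choices.append("fractal" if rng.random() < p else "square")
    return choices


def _rl_choice_draws(
    params: _rl.RLParams, schedule: TrialSchedule, rng: np.random.Generator
) -> list:
    values: dict = {}
    choices = []
    for ev in schedule.events:
        if isinstance(ev, ObservationEvent):
            v = values.get(ev.fractal_id, params.v0)
            values[ev.fractal_id] = _rl.td_update(v, int(ev.outcome), params)
        else:
            v = values.get(ev.fractal_id, params.v0)
            p = _rl.rl_choice_prob(v, ev.square_prob, params.tau, schedule.valence)
            choices.append("fractal" if rng.random() < p else "square")
    return choices


def simulate_subject(
    params,
    schedule: TrialSchedule,
    agent_type: str,
    rng: np.random.Generator,
    subject_id: str = "s0",
    trait_score: Union[int, None] = None,
) -> SubjectData:
    """Simulate one subject's choices by sampling from the agent's policy.

    ``params`` is a :class:`~optiprior.bayes.BayesParams` for ``agent_type
    'bayes'`` or an :class:`~optiprior.rl.RLParams` for ``'rl'``.  At each
    decision the agent's choice probability is evaluated from the evidence
    (or learned values) accumulated so far and a choice is sampled.
    """
    if agent_type == "bayes":
        choices = _bayes_choice_draws(params, schedule, rng)
        true_params = {
            "alpha": params.alpha,
            "beta": params.beta,
            "gamma": params.gamma,
            "prior_mean": params.prior_mean,
        }
    elif agent_type == "rl":
        choices = _rl_choice_draws(params, schedule, rng)
        true_params = {
            "variant": params.variant,
            "eps_pos": params.eps_pos,
            "eps_neg": params.eps_neg,
            "v0": params.v0,
            "tau": params.tau,
        }
    else:
        raise ValueError("agent_type must be 'bayes' or 'rl'")
    return SubjectData(
        subject_id=subject_id,
        schedule=schedule,
        choices=choices,
        trait_score=trait_score,
        true_params=true_params,
    )


def generate_cohort(config: CohortConfig) -> list:
    """Generate a full synthetic cohort: parameters, schedules, choices.

    Each subject gets an independent, freshly randomized schedule (as in the
    experiment, where the task was generated per participant).  Reproducible
    under ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    table = draw_subject_params(config, rng)
    task_cfg = design_config(config.design)
    cohort = []
    for i, row in table.iterrows():
        schedule = generate_schedule(task_cfg, rng)
        if config.agent_type == "bayes":
            params = BayesParams(row["alpha"], row["beta"], row["gamma"])
        else:
            # TD agent whose initial value plays the role of the prior mean
            params = _rl.RLParams.make(
                "RL_b", v0=float(np.clip(row["prior_mean"], 0.0, 1.0)),
                tau=row["gamma"],
            )
        subj = simulate_subject(
            params,
            schedule,
            config.agent_type,
            rng,
            subject_id=f"s{i:03d}",
            trait_score=int(row["trait_score"]),
        )
        cohort.append(subj)
    return cohort
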