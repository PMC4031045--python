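"""Temporal-difference learning observers with optional asymmetric rates.

Each fractal's value starts at ``v0`` and is updated after every observation
by the prediction error ``delta = r - V`` scaled by a learning rate that may
differ for better-than-expected (``eps_pos``, delta > 0) and
worse-than-expected (``eps_neg``, delta < 0) outcomes.  Choices follow the
same logistic softmax as the Bayesian observer, with steepness ``tau``.

Four nested variants are distinguished by which parameters are free:

=========  =======================  ====================
variant    learning rates           initial value v0
=========  =======================  ====================
RL_eps     one shared rate, free    fixed at 0.5
RL_2       eps_pos, eps_neg free    fixed at 0.5
RL_2b      eps_pos, eps_neg free    free
RL_b       shared rate fixed 0.1    free
=========  =======================  ====================

``tau`` is free in every variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import expit, log_expit

from .task import SubjectData, summarize_decisions

__all__ = [
    "RLParams",
    "RL_VARIANTS",
    "td_update",
    "value_after",
    "rl_choice_prob",
    "rl_log_likelihood",
]

RL_VARIANTS = ("RL_eps", "RL_2", "RL_2b", "RL_b")
FIXED_EPS_RL_B = 0.1
FIXED_V0 = 0.5


@dataclass(frozen=True)
class RLParams:
    variant: str
    eps_pos: float
    eps_neg: float
    v0: float
    tau: float

    def __post_init__(self) -> None:
        if self.variant not in RL_VARIANTS:
            raise ValueError(f"variant must be one of {RL_VARIANTS}")
        for name, val in (("eps_pos", self.eps_pos), ("eps_neg", self.eps_neg)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError("v0 must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.variant in ("RL_eps", "RL_b") and self.eps_pos != self.eps_neg:
            raise ValueError(f"{self.variant} uses a single shared learning rate")
        if self.variant in ("RL_eps", "RL_2") and self.v0 != FIXED_V0:
            raise ValueError(f"{self.variant} fixes v0 at {FIXED_V0}")
        if self.variant == "RL_b" and self.eps_pos != FIXED_EPS_RL_B:
            raise ValueError(f"RL_b fixes the learning rate at {FIXED_EPS_RL_B}")

    @classmethod
    def make(cls, variant: str, *, eps: float = None, eps_pos: float = None,
             eps_neg: float = None, v0: float = None, tau: float = 1.0) -> "RLParams":
        """Build parameters for a variant from just its free values."""
        if variant == "RL_eps":
            return cls(variant, eps, eps, FIXED_V0, tau)
        if variant == "RL_2":
            return cls(variant, eps_pos, eps_neg, FIXED_V0, tau)
        if variant == "RL_2b":
            return cls(variant, eps_pos, eps_neg, v0, tau)
        if variant == "RL_b":
            return cls(variant, FIXED_EPS_RL_B, FIXED_EPS_RL_B, v0, tau)
        raise ValueError(f"unknown variant {variant!r}")


def td_update(v: float, r: int, params: RLParams) -> float:
    """One prediction-error update: v + eps(delta) * delta with delta = r - v.

    A zero prediction error takes the eps_pos branch by convention; the
    update is zero either way.
    """
    delta = r - v
    eps = params.eps_pos if delta >= 0 else params.eps_neg
    return v + eps * delta


def value_after(outcomes: Iterable[int], params: RLParams) -> float:
    """Value after folding a fractal's observed outcome sequence from v0."""
    v = params.v0
    for r in outcomes:
        v = td_update(v, r, params)
    return v


def rl_choice_prob(v, b, tau, valence: str = "reward"):
    """Softmax probability of choosing the fractal given its learned value."""
    sign = 1.0 if valence == "reward" else -1.0
    return expit(sign * tau * (np.asarray(v, dtype=float) - b))


def rl_log_likelihood(params: RLParams, data: SubjectData) -> float:
    """Log-likelihood of the recorded choices under the TD observer.

    Values evolve over each fractal's observation screens in schedule order;
    each decision is scored with the fractal's value at that point.  Unlike
    the Bayesian observer, the result depends on outcome order whenever
    eps_pos != eps_neg.
    """
    summaries = summarize_decisions(data.schedule)
    v = np.array([value_after(s.outcomes, params) for s in summaries])
    b = np.array([s.square_prob for s in summaries])
    chose_fractal = np.array([c == "fractal" for c in data.choices], dtype=bool)
    sign = 1.0 if data.schedule.valence == "reward" else -1.0
    z = sign * params.tau * (v - b)
    return float(np.sum(log_expit(np.where(chose_fractal, z, -z))))
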