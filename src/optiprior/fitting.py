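"""Per-subject maximum-likelihood fitting, BIC, and model comparison.

Six models can be fitted to a subject's trial log:

* ``bayes_full`` — Beta-prior observer, free (alpha, beta, gamma);
* ``bayes_jeffreys`` — the non-informative reference: alpha = beta = 0.5
  fixed (Jeffreys prior), only gamma free;
* ``RL_eps`` / ``RL_2`` / ``RL_2b`` / ``RL_b`` — the TD-learning variants.

Positive parameters (alpha, beta, gamma, tau) are optimized on the log scale
so box bounds respect positivity; learning rates and v0 are optimized
directly on [0, 1].  Each fit runs a Latin-hypercube multi-start of bounded
L-BFGS-B local searches and keeps the best start.  The Bayesian models use
an analytic gradient; the TD models use finite differences.

The Bayesian information criterion is computed as k * ln(n) - 2 * logL with
n the number of decision events, since only decisions enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from scipy.stats import qmc

from .task import SubjectData, summarize_decisions
from . import rl as _rl

__all__ = [
    "FitResult",
    "ComparisonTable",
    "MODEL_NAMES",
    "fit_subject",
    "fit_cohort",
    "compute_bic",
    "compare_models",
]

# search bounds in natural space
ALPHA_BETA_BOUNDS = (0.05, 20.0)
GAMMA_BOUNDS = (0.01, 100.0)
TAU_BOUNDS = (0.01, 100.0)
EPS_BOUNDS = (1e-4, 1.0)
V0_BOUNDS = (1e-3, 1.0 - 1e-3)

JEFFREYS_SHAPE = 0.5


@dataclass(frozen=True)
class FitResult:
    """Outcome of one subject-level maximum-likelihood fit."""

    model_name: str
    params: dict
    log_lik: float
    n_free_params: int
    bic: float
    n_starts: int
    converged: bool
    start_objectives: tuple = field(default=(), repr=False)


def compute_bic(log_lik: float, k: int, n_decisions: int) -> float:
    """Bayesian information criterion, k * ln(n) - 2 * logL (lower is better)."""
    if n_decisions < 1:
        raise ValueError("BIC needs at least one decision event")
    return k * float(np.log(n_decisions)) - 2.0 * log_lik


def _choice_sign(data: SubjectData) -> np.ndarray:
    """Per-decision sign m_d: +1 for scoring the chosen-fractal branch."""
    sign = 1.0 if data.schedule.valence == "reward" else -1.0
    chose = np.array([c == "fractal" for c in data.choices], dtype=float)
    return sign * (2.0 * chose - 1.0)


def _bayes_objective(data: SubjectData, fix_jeffreys: bool) -> Callable:
    """Negative log-likelihood (and gradient) in log-parameter space."""
    summaries = summarize_decisions(data.schedule)
    n = np.array([s.n_rewards for s in summaries], dtype=float)
    N = np.array([s.n_shown for s in summaries], dtype=float)
    b = np.array([s.square_prob for s in summaries], dtype=float)
    m = _choice_sign(data)

    if fix_jeffreys:

        def fun(theta):
            gamma = np.exp(theta[0])
            tot = 2 * JEFFREYS_SHAPE + N
            c_hat = (JEFFREYS_SHAPE + n) / tot
            z = m * gamma * (c_hat - b)
            nll = -np.sum(log_expit(z))
            w = expit(-z)  # d logL / dz
            g_loggamma = np.sum(w * m * (c_hat - b)) * gamma
            return nll, -np.array([g_loggamma])

    else:

        def fun(theta):
            alpha, beta, gamma = np.exp(theta)
            tot = alpha + beta + N
            c_hat = (alpha + n) / tot
            z = m * gamma * (c_hat - b)
            nll = -np.sum(log_expit(z))
            w = expit(-z)
            dz_dchat = m * gamma
            dchat_da = (beta + N - n) / tot**2
            dchat_db = -(alpha + n) / tot**2
            g = np.array(
                [
                    np.sum(w * dz_dchat * dchat_da) * alpha,
                    np.sum(w * dz_dchat * dchat_db) * beta,
                    np.sum(w * m * (c_hat - b)) * gamma,
                ]
            )
            return nll, -g

    return fun


def _rl_objective(data: SubjectData, variant: str) -> Callable:
    summaries = summarize_decisions(data.schedule)
    outcome_seqs = [s.outcomes for s in summaries]
    b = np.array([s.square_prob for s in summaries], dtype=float)
    m = _choice_sign(data)

    def fun(theta):
        params = _rl_params_from_theta(variant, theta)
        v = np.array([_rl.value_after(seq, params) for seq in outcome_seqs])
        z = m * params.tau * (v - b)
        return -np.sum(log_expit(z))

    return fun


def _rl_params_from_theta(variant: str, theta: np.ndarray) -> _rl.RLParams:
    if variant == "RL_eps":
        return _rl.RLParams.make(variant, eps=theta[0], tau=np.exp(theta[1]))
    if variant == "RL_2":
        return _rl.RLParams.make(
            variant, eps_pos=theta[0], eps_neg=theta[1], tau=np.exp(theta[2])
        )
    if variant == "RL_2b":
        return _rl.RLParams.make(
            variant,
            eps_pos=theta[0],
            eps_neg=theta[1],
            v0=theta[2],
            tau=np.exp(theta[3]),
        )
    if variant == "RL_b":
        return _rl.RLParams.make(variant, v0=theta[0], tau=np.exp(theta[1]))
    raise ValueError(f"unknown RL variant {variant!r}")


def _log_bounds(lo_hi) -> tuple:
    return (np.log(lo_hi[0]), np.log(lo_hi[1]))


@dataclass(frozen=True)
class _ModelSpec:
    n_free: int
    bounds: tuple  # per-theta (lo, hi) in the optimized space
    build_objective: Callable  # data -> fun(theta) [-> nll or (nll, grad)]
    with_grad: bool
    to_params: Callable  # theta -> natural-space parameter dict


def _bayes_full_params(theta):
    alpha, beta, gamma = np.exp(theta)
    return {
        "alpha": float(alpha),
        "beta": float(beta),
        "gamma": float(gamma),
        "prior_mean": float(alpha / (alpha + beta)),
    }


def _bayes_jeffreys_params(theta):
    return {
        "alpha": JEFFREYS_SHAPE,
        "beta": JEFFREYS_SHAPE,
        "gamma": float(np.exp(theta[0])),
        "prior_mean": 0.5,
    }


def _rl_param_dict(variant):
    def to_params(theta):
        p = _rl_params_from_theta(variant, theta)
        return {
            "eps_pos": float(p.eps_pos),
            "eps_neg": float(p.eps_neg),
            "v0": float(p.v0),
            "tau": float(p.tau),
        }

    return to_params


MODELS = {
    "bayes_full": _ModelSpec(
        n_free=3,
        bounds=(
            _log_bounds(ALPHA_BETA_BOUNDS),
            _log_bounds(ALPHA_BETA_BOUNDS),
            _log_bounds(GAMMA_BOUNDS),
        ),
        build_objective=lambda d: _bayes_objective(d, fix_jeffreys=False),
        with_grad=True,
        to_params=_bayes_full_params,
    ),
    "bayes_jeffreys": _ModelSpec(
        n_free=1,
        bounds=(_log_bounds(GAMMA_BOUNDS),),
        build_objective=lambda d: _bayes_objective(d, fix_jeffreys=True),
        with_grad=True,
        to_params=_bayes_jeffreys_params,
    ),
    "RL_eps": _ModelSpec(
        n_free=2,
        bounds=(EPS_BOUNDS, _log_bounds(TAU_BOUNDS)),
        build_objective=lambda d: _rl_objective(d, "RL_eps"),
        with_grad=False,
        to_params=_rl_param_dict("RL_eps"),
    ),
    "RL_2": _ModelSpec(
        n_free=3,
        bounds=(EPS_BOUNDS, EPS_BOUNDS, _log_bounds(TAU_BOUNDS)),
        build_objective=lambda d: _rl_objective(d, "RL_2"),
        with_grad=False,
        to_params=_rl_param_dict("RL_2"),
    ),
    "RL_2b": _ModelSpec(
        n_free=4,
        bounds=(EPS_BOUNDS, EPS_BOUNDS, V0_BOUNDS, _log_bounds(TAU_BOUNDS)),
        build_objective=lambda d: _rl_objective(d, "RL_2b"),
        with_grad=False,
        to_params=_rl_param_dict("RL_2b"),
    ),
    "RL_b": _ModelSpec(
        n_free=2,
        bounds=(V0_BOUNDS, _log_bounds(TAU_BOUNDS)),
        build_objective=lambda d: _rl_objective(d, "RL_b"),
        with_grad=False,
        to_params=_rl_param_dict("RL_b"),
    ),
}

MODEL_NAMES = tuple(MODELS)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def fit_subject(
    model_name: str,
    data: SubjectData,
    n_starts: int = 20,
    rng: Union[np.random.Generator, int, None] = 0,
) -> FitResult:
    """Fit one model to one subject by multi-start bounded MLE.

    Starts are a Latin-hypercube sample of the (transformed) parameter box,
    so the result is deterministic under a fixed ``rng`` seed.  A fit where
    no start converges is returned with ``converged=False`` rather than
    raising.
    """
    if model_name not in MODELS:
        raise KeyError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    if data.n_decisions < 1:
        raise ValueError("subject has no decision events to fit")
    spec = MODELS[model_name]
    rng = _as_rng(rng)

    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    sampler = qmc.LatinHypercube(d=len(spec.bounds), seed=rng)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)

    objective = spec.build_objective(data)
    best = None
    objectives = []
    any_success = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac=spec.with_grad,
            bounds=list(spec.bounds),
        )
        objectives.append(float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    log_lik = -float(best.fun)
    return FitResult(
        model_name=model_name,
        params=spec.to_params(best.x),
        log_lik=log_lik,
        n_free_params=spec.n_free,
        bic=compute_bic(log_lik, spec.n_free, data.n_decisions),
        n_starts=n_starts,
        converged=any_success,
        start_objectives=tuple(objectives),
    )


def fit_cohort(
    model_name: str,
    cohort: Sequence[SubjectData],
    n_starts: int = 20,
    rng: Union[np.random.Generator, int, None] = 0,
) -> list:
    """Fit one model independently to every subject of a cohort."""
    rng = _as_rng(rng)
    seeds = rng.spawn(len(cohort))
    return [
        fit_subject(model_name, subj, n_starts=n_starts, rng=child)
        for subj, child in zip(cohort, seeds)
    ]


@dataclass(frozen=True)
class ComparisonTable:
    """Per-subject BIC winners and per-model group summaries."""

    per_subject: pd.DataFrame  # columns: subject, winner, tie, bic_<model>...
    summary: pd.DataFrame  # index: model; columns: mean_bic, frac_preferred


def compare_models(
    fits_by_subject: Sequence[Sequence[FitResult]],
    tie_tol: float = 1e-9,
) -> ComparisonTable:
    """Rank fitted models per subject by BIC (lower wins).

    BIC ties within ``tie_tol`` are broken toward the model with fewer free
    parameters and flagged in the ``tie`` column.
    """
    rows = []
    model_names = [f.model_name for f in fits_by_subject[0]]
    for i, fits in enumerate(fits_by_subject):
        if len(fits) < 2:
            raise ValueError("need at least two fitted models per subject")
        bics = {f.model_name: f.bic for f in fits}
        best_bic = min(bics.values())
        tied = [f for f in fits if f.bic <= best_bic + tie_tol]
        winner = min(tied, key=lambda f: (f.n_free_params, f.model_name))
        rows.append(
            {
                "subject": i,
                "winner": winner.model_name,
                "tie": len(tied) > 1,
                **{f"bic_{name}": bics[name] for name in model_names},
            }
        )
    per_subject = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean_bic": {
                name: per_subject[f"bic_{name}"].mean() for name in model_names
            },
            "frac_preferred": {
                name: (per_subject["winner"] == name).mean()
                for name in model_names
            },
        }
    )
    summary.index.name = "model"
    return ComparisonTable(per_subject=per_subject, summary=summary)
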