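"""Group-level statistics: performance curves, trait correlations, splits.

Implements the cohort-level analyses run on trial logs (real-format or
synthetic): the 50%-performance exclusion rule, performance as a function of
the observed-rate-minus-square-probability difference, the Pearson
correlation between trait optimism and the fitted prior mean (with a
Bonferroni correction over the questionnaire battery's 42 comparisons),
Fisher r-to-z comparison of correlations across experiments,
optimist/pessimist group splits with Welch t-tests on fitted parameters, and
the under-/over-observed stratification that probes how the prior's
influence depends on the amount of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .task import SubjectData, summarize_decisions
from .fitting import FitResult

__all__ = [
    "BONFERRONI_M",
    "ExclusionResult",
    "PerformanceCurve",
    "CorrelationResult",
    "GroupSplitResult",
    "UnderOverResult",
    "empirical_accuracy",
    "exclude_low_performers",
    "performance_curve",
    "correlate_trait_prior",
    "fisher_z_compare",
    "optimist_mask",
    "split_group_tests",
    "under_over_observed_analysis",
]

# size of the questionnaire-battery comparison family used for Bonferroni
BONFERRONI_M = 42


def empirical_accuracy(subject: SubjectData) -> tuple:
    """Fraction of decisions where the empirically better option was chosen.

    The better option has the higher observed outcome rate n/N versus the
    square's stated probability (lower, under punishment avoidance).  Ties
    and never-observed fractals are excluded from the denominator.  Returns
    ``(accuracy, n_scored)``; accuracy is NaN when every decision is a tie.
    """
    punish = subject.schedule.valence == "punishment"
    n_correct = 0
    n_scored = 0
    for s, choice in zip(summarize_decisions(subject.schedule), subject.choices):
        if s.n_shown == 0:
            continue
        rate = s.n_rewards / s.n_shown
        if rate == s.square_prob:
            continue
        fractal_better = (rate < s.square_prob) if punish else (rate > s.square_prob)
        n_scored += 1
        if (choice == "fractal") == fractal_better:
            n_correct += 1
    if n_scored == 0:
        return float("nan"), 0
    return n_correct / n_scored, n_scored


@dataclass(frozen=True)
class ExclusionResult:
    kept: list
    excluded: list
    flagged_all_ties: list  # retained but unscorable (every decision tied)


def exclude_low_performers(
    cohort: Sequence[SubjectData], threshold: float = 0.5
) -> ExclusionResult:
    """Drop subjects whose empirical accuracy does not exceed ``threshold``."""
    kept, excluded, flagged = [], [], []
    for subj in cohort:
        acc, n_scored = empirical_accuracy(subj)
        if n_scored == 0:
            kept.append(subj)
            flagged.append(subj.subject_id)
        elif acc > threshold:
            kept.append(subj)
        else:
            excluded.append(subj)
    return ExclusionResult(kept=kept, excluded=excluded, flagged_all_ties=flagged)


@dataclass(frozen=True)
class PerformanceCurve:
    """Fraction of fractal choices binned by Delta = n/N - b over [-1, 1]."""

    bin_edges: np.ndarray
    fraction_chose_fractal: np.ndarray  # NaN for empty bins
    counts: np.ndarray
    n_dropped_prior_only: int
    group_label: str = "all"


def performance_curve(
    subjects: Sequence[SubjectData],
    bin_width: float = 0.2,
    group_label: str = "all",
) -> PerformanceCurve:
    """Pool all decisions and bin the fractal-choice indicator by Delta.

    Decisions on never-observed fractals have no observed rate; they are
    dropped from the curve (their count is reported) but are still used in
    likelihood fitting elsewhere.
    """
    n_bins = int(round(2.0 / bin_width))
    edges = -1.0 + bin_width * np.arange(n_bins + 1)
    deltas, chose = [], []
    dropped = 0
    for subj in subjects:
        for s, choice in zip(summarize_decisions(subj.schedule), subj.choices):
            if s.n_shown == 0:
                dropped += 1
                continue
            deltas.append(s.n_rewards / s.n_shown - s.square_prob)
            chose.append(choice == "fractal")
    deltas = np.asarray(deltas)
    chose = np.asarray(chose, dtype=float)
    idx = np.clip(np.digitize(deltas, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=chose, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PerformanceCurve(
        bin_edges=edges,
        fraction_chose_fractal=frac,
        counts=counts,
        n_dropped_prior_only=dropped,
        group_label=group_label,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    p_adjusted: float  # Bonferroni over the questionnaire battery
    n: int


def correlate_trait_prior(
    trait_scores: Sequence[float],
    fitted_prior_means: Sequence[float],
    n_comparisons: int = BONFERRONI_M,
) -> CorrelationResult:
    """Pearson correlation of trait score with fitted prior mean.

    The two-sided p-value uses the exact t transform with n - 2 degrees of
    freedom; the adjusted value applies a Bonferroni factor for the full
    questionnaire comparison family (42 by default).
    """
    x = np.asarray(trait_scores, dtype=float)
    y = np.asarray(fitted_prior_means, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic),
        p=float(res.pvalue),
        p_adjusted=min(1.0, n_comparisons * float(res.pvalue)),
        n=len(x),
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple:
    """Two-sample Fisher r-to-z test for a difference between correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if min(n1, n2) <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def optimist_mask(trait_scores: Sequence[float]) -> np.ndarray:
    """Boolean mask of optimists: trait strictly above the cohort mean.

    Scores equal to the mean count as pessimists.
    """
    scores = np.asarray(trait_scores, dtype=float)
    return scores > scores.mean()


@dataclass(frozen=True)
class GroupSplitResult:
    """Optimist/pessimist means, SDs and Welch t-tests per fitted parameter."""

    table: pd.DataFrame  # rows: parameter; columns per-group mean/sd, t, p
    n_optimists: int
    n_pessimists: int


def split_group_tests(
    cohort: Sequence[SubjectData], fits: Sequence[FitResult]
) -> GroupSplitResult:
    """Split at the mean trait score and compare fitted parameters by group."""
    if len(cohort) != len(fits):
        raise ValueError("cohort and fits must be aligned")
    traits = [s.trait_score for s in cohort]
    if any(t is None for t in traits):
        raise ValueError("every subject needs a trait score")
    opt = optimist_mask(traits)
    if opt.sum() < 2 or (~opt).sum() < 2:
        raise ValueError("each group needs at least 2 members")

    param_names = list(fits[0].params)
    values = {
        name: np.array([f.params[name] for f in fits]) for name in param_names
    }
    values["trait_score"] = np.asarray(traits, dtype=float)
    rows = {}
    for name in ["trait_score"] + param_names:
        v = values[name]
        a, b = v[opt], v[~opt]
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows[name] = {
            "optimist_mean": a.mean(),
            "optimist_sd": a.std(ddof=1),
            "pessimist_mean": b.mean(),
            "pessimist_sd": b.std(ddof=1),
            "t": float(t),
            "p": float(p),
        }
    return GroupSplitResult(
        table=pd.DataFrame(rows).T,
        n_optimists=int(opt.sum()),
        n_pessimists=int((~opt).sum()),
    )


@dataclass(frozen=True)
class UnderOverResult:
    """Optimist-pessimist contrasts within evidence strata.

    ``p_under`` / ``p_over`` are two-sided Welch tests of the groups'
    fractal-choice rates among decisions whose fractal was observed strictly
    fewer / strictly more than ``threshold`` times; decisions at exactly the
    threshold belong to neither stratum.  ``p_interaction`` is the one-tailed
    Welch test that the optimist-pessimist difference is larger for
    under-observed fractals, applied to per-subject (under - over) scores.
    """

    threshold: int
    t_under: float
    p_under: float
    t_over: float
    p_over: float
    t_interaction: float
    p_interaction: float
    per_subject: pd.DataFrame
    n_dropped_under: int
    n_dropped_over: int


def _stratum_bias(subject: SubjectData, lo: bool, threshold: int) -> float:
    """Fraction of fractal choices among under- (lo) or over-observed fractals."""
    picks = []
    for s, choice in zip(summarize_decisions(subject.schedule), subject.choices):
        in_stratum = s.n_shown < threshold if lo else s.n_shown > threshold
        if in_stratum:
            picks.append(choice == "fractal")
    return float(np.mean(picks)) if picks else float("nan")


def under_over_observed_analysis(
    cohort: Sequence[SubjectData], threshold: int = 4
) -> UnderOverResult:
    """Test whether the optimist-pessimist gap shrinks with more evidence.

    Requires variable presentation counts (the mean-4 interleaved design);
    subjects lacking decisions in a stratum are dropped from that stratum's
    test, and their number reported.
    """
    traits = [s.trait_score for s in cohort]
    if any(t is None for t in traits):
        raise ValueError("every subject needs a trait score")
    opt = optimist_mask(traits)
    under = np.array([_stratum_bias(s, True, threshold) for s in cohort])
    over = np.array([_stratum_bias(s, False, threshold) for s in cohort])
    per_subject = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "trait_score": traits,
            "optimist": opt,
            "under_bias": under,
            "over_bias": over,
        }
    )

    def welch(mask_vals, alternative="two-sided"):
        vals, grp = mask_vals
        ok = ~np.isnan(vals)
        a, b = vals[ok & grp], vals[ok & ~grp]
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(t), float(p), int((~ok).sum())

    t_u, p_u, drop_u = welch((under, opt))
    t_o, p_o, drop_o = welch((over, opt))
    diff = under - over
    t_i, p_i, _ = welch((diff, opt), alternative="greater")
    return UnderOverResult(
        threshold=threshold,
        t_under=t_u,
        p_under=p_u,
        t_over=t_o,
        p_over=p_o,
        t_interaction=t_i,
        p_interaction=p_i,
        per_subject=per_subject,
        n_dropped_under=drop_u,
        n_dropped_over=drop_o,
    )
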