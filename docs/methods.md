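# Methods

## Task model

A session consists of observation screens (a fractal followed by a binary
outcome) and exactly one decision screen per fractal (fractal vs a square
of stated probability). Defaults follow the reward-seeking design: 60
fractals, hidden outcome probabilities `c_i ~ U(0,1)`, presentation counts
from Poisson(4) conditioned on being > 2 (sampled by rejection, which is
exact), square probabilities uniform on the 11-point grid
{0.0, 0.1, …, 1.0}. Two arrangements are supported:

* **interleaved** — fractals are partitioned into consecutive groups of 5;
  a group's observation screens are shuffled and each fractal's decision
  screen is inserted at a uniformly random position after its last
  observation. The grid endpoints 0 and 1 are included because the square's
  probability is displayed as 0–10 filled dots.
* **blocked** — each fractal's observations are contiguous and its decision
  follows immediately. The lag between a fractal's last observation and its
  decision is zero by choice; nothing in the models depends on it because
  decisions yield no feedback.

The screen side of the fractal is recorded for log fidelity but ignored by
all models. A punishment variant relabels outcomes as punishments without
touching the schedule structure.

## Observer models

**Bayesian.** Beta(α, β) prior per fractal, shared across fractals within a
subject; the decision variable is the posterior mean
`ĉ_i = (α + n_i)/(α + β + N_i)`, where `(n_i, N_i)` count outcomes in the
observation screens preceding the decision. Decisions contribute no
evidence (the task gives no feedback after them). Choice of the fractal has
probability `expit(γ(ĉ_i − b_i))`; under punishment avoidance the sign is
flipped, `expit(γ(b_i − ĉ_i))` — the minimal symmetric extension of the
reward rule. γ = 0 is random choice; γ is capped at 100 in fitting, and all
logistic terms are evaluated with `log_expit` for stability.

**TD.** Per-fractal values start at `v₀` and update only on observation
screens: `V ← V + ε(δ)δ`, `δ = r − V`, with `ε = ε₊` for `δ > 0` and `ε₋`
for `δ < 0`. A zero prediction error is assigned to the `ε₊` branch for
determinism; the update is zero either way. Variants: `RL_eps` (one free
rate, `v₀ = 0.5`), `RL_2` (two free rates, `v₀ = 0.5`), `RL_2b` (two rates
and `v₀` free), `RL_b` (`v₀` free, rate fixed at 0.1). τ is free in all.
For binary outcomes and `v₀, ε ∈ [0,1]`, values provably remain in [0,1].

## Fitting

Per-subject maximum likelihood with bounded L-BFGS-B from 20
Latin-hypercube starts (deterministic under a seed). Positive parameters
are optimized on the log scale: α, β ∈ [0.05, 20], γ, τ ∈ [0.01, 100];
rates and `v₀` are box-bounded on [0, 1] directly. The search-space bounds
are a package choice — no canonical values exist — and are wide relative to
the fitted values they produce. The Bayesian models use an analytic
gradient of the negative log-likelihood in transformed space; the TD models
use finite differences. A fit where no start converges is returned flagged
rather than raised. BIC uses `n = number of decision events` (only
decisions enter the likelihood); BIC ties are broken toward fewer free
parameters and flagged.

## Synthetic cohorts

`(trait, prior mean)` are drawn from a bivariate Gaussian with marginal
moments trait 14.7 (SD 4.42), prior mean 0.42 (SD 0.23), correlation 0.44
by default — the reward-seeking study conditions — then traits are rounded
to integers and clipped to [0, 24] and prior means clipped to
(0.01, 0.99); the planted correlation refers to the pre-rounding values
(the post-processing changes it by < 0.01). Beta shapes follow from the
prior mean and a shared concentration `α + β = 2.0`; the concentration is a
free scalar because only the prior's mean is constrained by the study
conditions, and 2.0 keeps the prior weak (two pseudo-observations), its
influence visible at ~4 observations and faint at ~10. Softmax steepness is
truncated-normal positive with location 7.88 and scale 3.93. Each subject
receives a freshly randomized schedule, and choices are sampled from the
generating agent's policy (Bayesian by default; a TD agent with `v₀` tied
to the drawn prior mean is available).

What the generator does **not** emulate: questionnaire item-level
structure, any latent heterogeneity family beyond Gaussian/truncated-normal
(the real population's distribution of γ is unknown), response times,
attention lapses, or learning-rate asymmetries in the generating agent.
Passing recovery tests therefore show that the pipeline is self-consistent
under these idealized conditions, not that real data would identify the
parameters equally well.

## Group analyses

* **Exclusion**: a subject is dropped when the fraction of "empirically
  correct" choices (picking the larger of observed rate `n_i/N_i` vs `b_i`;
  the smaller, under punishment) is ≤ 0.5; ties and never-observed fractals
  are excluded from the denominator; an all-tie subject is retained and
  flagged.
* **Performance curves**: fractal-choice rate binned by
  `Δ = n_i/N_i − b_i` with bin width 0.2 over [−1, 1] (configurable);
  decisions on never-observed fractals are dropped from curves (count
  reported) but retained in fitting. Empty bins report NaN, not zero.
* **Correlation**: Pearson r with the exact t-transform p (n − 2 df);
  Bonferroni multiplier 42, the size of the questionnaire-battery family.
* **Fisher r-to-z**: `Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`,
  two-sided normal p; sample sizes default to the full recruited n per
  experiment.
* **Group split**: optimists are strictly above the cohort-mean trait
  score; scores equal to the mean count as pessimists. Parameters are
  compared with Welch t-tests.
* **Under/over-observed**: per subject, the fractal-choice rate among
  decisions whose fractal was observed strictly fewer than 4 vs strictly
  more than 4 times (exactly 4 belongs to neither stratum); two-sided Welch
  tests per stratum between groups, and a one-tailed Welch test on the
  per-subject (under − over) difference for the claim that the gap is
  larger with sparse evidence. The one-tailed construction is a package
  choice; only the test family is canonical.

## Problem sizes and stochastic checks

Replicate-level checks (recovery, washout, stratification) use 20 replicate
cohorts of 51 subjects with 20 optimizer starts per fit — the same cohort
size as the study conditions. The "strong planted effect" used for the
stratification check sets the latent trait-prior correlation to 0.8, since
the signature under test concerns a pronounced group difference.

## Known limitations

* With 60 decisions and a weak (concentration-2) prior, the MLE of the
  prior mean is noisy: its correlation with the generating prior mean is
  ≈ 0.7, so an observed trait-prior correlation attenuates to roughly 70%
  of the planted latent value. Power to detect the planted 0.44 at n = 51
  is therefore meaningfully below its no-attenuation value, and the washout
  contrast between sparse and rich designs is partial rather than total:
  the prior's per-decision weight falls from ≈ 1/3 (4 observations) to
  ≈ 1/6 (10 observations), not to zero. Raising the concentration
  strengthens identifiability; this sensitivity is exercised in the tests.
* Group-mean BICs depend on the generating population and are not
  comparable across cohorts with different γ distributions.
* The TD models are fitted with numerical gradients and are slower to fit;
  they are intended for model comparison, not large-scale recovery studies.
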