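"""Pavlovian conditioning task: schedules of observation and decision screens.

The task presents fractal conditioned stimuli (CS), each paired with a binary
outcome (reward, or punishment in the aversive variant) at a fixed but hidden
per-fractal probability ``c_i`` drawn uniformly on [0, 1].  After a fractal has
been observed its allotted number of times (truncated-Poisson distributed), a
single decision screen asks the subject to choose between that fractal and a
colored square whose outcome probability ``b_i`` is stated explicitly (a value
on a 0.1 grid).  Schedules come in two arrangements: observation screens
randomly interleaved within consecutive groups of five fractals, or blocked
(all of a fractal's observations contiguous, decision immediately after).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "TaskConfig",
    "ObservationEvent",
    "DecisionEvent",
    "TrialSchedule",
    "DecisionSummary",
    "SubjectData",
    "sample_fractal_probs",
    "sample_presentation_counts",
    "build_schedule",
    "generate_schedule",
    "flip_valence",
    "summarize_decisions",
]

VALENCES = ("reward", "punishment")
INTERLEAVINGS = ("interleaved_groups_of_5", "blocked")


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters for one subject-session.

    ``presentation_min`` is the strict lower cut of the truncated Poisson:
    counts are redrawn until strictly greater than it, so the default of 2
    guarantees every fractal is observed at least 3 times.
    """

    n_fractals: int = 60
    mean_presentations: float = 4.0
    presentation_min: int = 2
    interleaving: str = "interleaved_groups_of_5"
    valence: str = "reward"
    square_prob_grid_step: float = 0.1
    group_size: int = 5
    rng_seed: Union[int, None] = None

    def __post_init__(self) -> None:
        if self.n_fractals <= 0:
            raise ValueError("n_fractals must be positive")
        if self.mean_presentations <= 0:
            raise ValueError("mean_presentations must be positive")
        if self.interleaving not in INTERLEAVINGS:
            raise ValueError(f"interleaving must be one of {INTERLEAVINGS}")
        if self.valence not in VALENCES:
            raise ValueError(f"valence must be one of {VALENCES}")
        if not 0 < self.square_prob_grid_step <= 1:
            raise ValueError("square_prob_grid_step must be in (0, 1]")
        if (
            self.interleaving == "interleaved_groups_of_5"
            and self.n_fractals % self.group_size != 0
        ):
            raise ValueError(
                "group size must divide n_fractals in interleaved mode"
            )

    @property
    def square_prob_grid(self) -> np.ndarray:
        """The admissible square probabilities: multiples of the grid step in [0, 1]."""
        n_levels = int(round(1.0 / self.square_prob_grid_step)) + 1
        return np.round(np.arange(n_levels) * self.square_prob_grid_step, 12)


@dataclass(frozen=True)
class ObservationEvent:
    """Passive presentation of a fractal followed by a binary outcome."""

    fractal_id: int
    outcome: int  # 1 = reward delivered (punishment delivered in aversive variant)
    side: str = "left"  # screen side; recorded for log fidelity, ignored by models


@dataclass(frozen=True)
class DecisionEvent:
    """Forced choice between the fractal and a square of stated probability."""

    fractal_id: int
    square_prob: float
    side: str = "left"


Event = Union[ObservationEvent, DecisionEvent]


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered events of one session plus the hidden per-fractal probabilities."""

    events: tuple
    fractal_probs: dict
    valence: str = "reward"

    @property
    def n_decisions(self) -> int:
        return sum(isinstance(e, DecisionEvent) for e in self.events)

    def validate(self) -> None:
        """Check the structural invariants of a well-formed schedule."""
        seen_decision: set = set()
        obs_counts: dict = {}
        for ev in self.events:
            if isinstance(ev, ObservationEvent):
                if ev.fractal_id in seen_decision:
                    raise ValueError(
                        f"observation of fractal {ev.fractal_id} after its decision"
                    )
                obs_counts[ev.fractal_id] = obs_counts.get(ev.fractal_id, 0) + 1
            else:
                if ev.fractal_id in seen_decision:
                    raise ValueError(f"fractal {ev.fractal_id} decided twice")
                seen_decision.add(ev.fractal_id)
        if seen_decision != set(self.fractal_probs):
            raise ValueError("every fractal must appear in exactly one decision")


@dataclass(frozen=True)
class DecisionSummary:
    """Evidence available at one decision: prefix counts and the outcome sequence."""

    fractal_id: int
    square_prob: float
    n_rewards: int
    n_shown: int
    outcomes: tuple  # ordered binary outcomes observed before the decision


@dataclass
class SubjectData:
    """One subject's trial log: schedule, realized choices, and trait score.

    ``choices`` is aligned with the decision events in schedule order and
    holds ``"fractal"`` or ``"square"``.
    """

    subject_id: str
    schedule: TrialSchedule
    choices: list
    trait_score: Union[int, None] = None
    true_params: Union[dict, None] = None

    def __post_init__(self) -> None:
        if len(self.choices) != self.schedule.n_decisions:
            raise ValueError("one choice required per decision event")

    @property
    def n_decisions(self) -> int:
        return self.schedule.n_decisions


def summarize_decisions(schedule: TrialSchedule) -> list:
    """Per-decision evidence summaries, in schedule order.

    Only observation screens preceding the decision contribute evidence; the
    task gives no feedback after decisions, so decisions add none.
    """
    history: dict = {}
    out = []
    for ev in schedule.events:
        if isinstance(ev, ObservationEvent):
            history.setdefault(ev.fractal_id, []).append(int(ev.outcome))
        else:
            seq = tuple(history.get(ev.fractal_id, ()))
            out.append(
                DecisionSummary(
                    fractal_id=ev.fractal_id,
                    square_prob=float(ev.square_prob),
                    n_rewards=int(sum(seq)),
                    n_shown=len(seq),
                    outcomes=seq,
                )
            )
    return out


def sample_fractal_probs(config: TaskConfig, rng: np.random.Generator) -> dict:
    """Draw each fractal's hidden outcome probability uniformly on [0, 1]."""
    probs = rng.uniform(0.0, 1.0, size=config.n_fractals)
    return {i: float(p) for i, p in enumerate(probs)}


def sample_presentation_counts(
    config: TaskConfig, rng: np.random.Generator
) -> dict:
    """Draw per-fractal presentation counts from a truncated Poisson.

    Counts follow Poisson(``mean_presentations``) conditioned on being
    strictly greater than ``presentation_min``, sampled by rejection (exact).
    """
    counts = np.empty(config.n_fractals, dtype=int)
    pending = np.ones(config.n_fractals, dtype=bool)
    while pending.any():
        draws = rng.poisson(config.mean_presentations, size=int(pending.sum()))
        idx = np.flatnonzero(pending)
        accept = draws > config.presentation_min
        counts[idx[accept]] = draws[accept]
        pending[idx[accept]] = False
    return {i: int(c) for i, c in enumerate(counts)}


def _sample_outcome(rng: np.random.Generator, p: float) -> int:
    return int(rng.random() < p)


def _square_prob(rng: np.random.Generator, grid: np.ndarray) -> float:
    return float(grid[rng.integers(len(grid))])


def _side(rng: np.random.Generator) -> str:
    return "left" if rng.random() < 0.5 else "right"


def build_schedule(
    config: TaskConfig,
    probs: dict,
    counts: dict,
    rng: np.random.Generator,
) -> TrialSchedule:
    """Assemble the ordered event sequence for one session.

    Interleaved mode partitions fractals into consecutive groups of
    ``group_size``; within a group the observation screens are shuffled and
    each fractal's single decision screen is inserted at a random position
    after its last observation.  Blocked mode presents each fractal's
    observations contiguously with its decision immediately after.
    """
    if set(probs) != set(counts):
        raise ValueError("probs and counts must cover the same fractal ids")
    grid = config.square_prob_grid
    events: list = []

    if config.interleaving == "blocked":
        order = rng.permutation(sorted(probs))
        for fid in order:
            fid = int(fid)
            for _ in range(counts[fid]):
                events.append(
                    ObservationEvent(fid, _sample_outcome(rng, probs[fid]), _side(rng))
                )
            events.append(DecisionEvent(fid, _square_prob(rng, grid), _side(rng)))
    else:
        ids = sorted(probs)
        for g in range(0, len(ids), config.group_size):
            group = ids[g : g + config.group_size]
            obs = [fid for fid in group for _ in range(counts[fid])]
            obs = [int(x) for x in rng.permutation(obs)]
            block: list = [
                ObservationEvent(fid, _sample_outcome(rng, probs[fid]), _side(rng))
                for fid in obs
            ]
            for fid in rng.permutation(group):
                fid = int(fid)
                last = max(
                    i
                    for i, ev in enumerate(block)
                    if isinstance(ev, ObservationEvent) and ev.fractal_id == fid
                )
                pos = int(rng.integers(last + 1, len(block) + 1))
                block.insert(
                    pos, DecisionEvent(fid, _square_prob(rng, grid), _side(rng))
                )
            events.extend(block)

    return TrialSchedule(
        events=tuple(events),
        fractal_probs=dict(probs),
        valence=config.valence,
    )


def generate_schedule(config: TaskConfig, rng: np.random.Generator) -> TrialSchedule:
    """Sample probabilities and counts, then build a full schedule."""
    probs = sample_fractal_probs(config, rng)
    counts = sample_presentation_counts(config, rng)
    return build_schedule(config, probs, counts, rng)


def flip_valence(schedule: TrialSchedule) -> TrialSchedule:
    """Reinterpret outcomes as punishments (or back); structure is untouched."""
    new = "punishment" if schedule.valence == "reward" else "reward"
    return replace(schedule, valence=new)
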