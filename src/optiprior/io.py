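"""Trial-log CSV and cohort manifest serialization.

One CSV row per event, columns::

    subject_id, event_index, event_type {obs, dec}, fractal_id,
    outcome {0, 1, NA}, square_prob {NA or grid value}, choice
    {fractal, square, NA}, side

A cohort directory holds one ``<subject_id>.csv`` per subject plus a
``manifest.json`` recording trait scores, generating parameters, hidden
fractal probabilities and the valence — everything needed to reconstruct
:class:`~optiprior.task.SubjectData` objects and to score parameter
recovery.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .task import (
    DecisionEvent,
    ObservationEvent,
    SubjectData,
    TrialSchedule,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "trial_log_frame",
    "subject_from_frame",
    "write_trial_log",
    "read_trial_log",
    "write_cohort",
    "read_cohort",
]

TRIAL_LOG_COLUMNS = [
    "subject_id",
    "event_index",
    "event_type",
    "fractal_id",
    "outcome",
    "square_prob",
    "choice",
    "side",
]


def trial_log_frame(subject: SubjectData) -> pd.DataFrame:
    """Flatten one subject's schedule and choices into the trial-log table."""
    rows = []
    choices = iter(subject.choices)
    for i, ev in enumerate(subject.schedule.events):
        if isinstance(ev, ObservationEvent):
            rows.append(
                (subject.subject_id, i, "obs", ev.fractal_id, ev.outcome,
                 np.nan, np.nan, ev.side)
            )
        else:
            rows.append(
                (subject.subject_id, i, "dec", ev.fractal_id, np.nan,
                 ev.square_prob, next(choices), ev.side)
            )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def subject_from_frame(
    frame: pd.DataFrame,
    fractal_probs: Union[dict, None] = None,
    valence: str = "reward",
    trait_score: Union[int, None] = None,
    true_params: Union[dict, None] = None,
) -> SubjectData:
    """Rebuild a SubjectData from a trial-log table.

    ``fractal_probs`` are not stored in the CSV (they are hidden from the
    subject); when absent, NaN placeholders are used so likelihoods — which
    never touch them — still work.
    """
    frame = frame.sort_values("event_index")
    events = []
    choices = []
    fractal_ids = set()
    for row in frame.itertuples(index=False):
        fid = int(row.fractal_id)
        side = row.side if isinstance(row.side, str) else "left"
        if row.event_type == "obs":
            events.append(ObservationEvent(fid, int(row.outcome), side))
        elif row.event_type == "dec":
            events.append(DecisionEvent(fid, float(row.square_prob), side))
            choices.append(str(row.choice))
            fractal_ids.add(fid)
        else:
            raise ValueError(f"unknown event_type {row.event_type!r}")
    if fractal_probs is None:
        fractal_probs = {fid: float("nan") for fid in sorted(fractal_ids)}
    schedule = TrialSchedule(
        events=tuple(events), fractal_probs=fractal_probs, valence=valence
    )
    return SubjectData(
        subject_id=str(frame["subject_id"].iloc[0]),
        schedule=schedule,
        choices=choices,
        trait_score=trait_score,
        true_params=true_params,
    )


def write_trial_log(subject: SubjectData, path: Union[str, Path]) -> None:
    trial_log_frame(subject).to_csv(path, index=False)


def read_trial_log(path: Union[str, Path], **kwargs) -> SubjectData:
    return subject_from_frame(pd.read_csv(path), **kwargs)


def write_cohort(cohort: Sequence[SubjectData], directory: Union[str, Path]) -> None:
    """Write one trial-log CSV per subject plus the manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    for subj in cohort:
        write_trial_log(subj, directory / f"{subj.subject_id}.csv")
        manifest["subjects"].append(
            {
                "subject_id": subj.subject_id,
                "trait_score": subj.trait_score,
                "true_params": subj.true_params,
                "valence": subj.schedule.valence,
                "fractal_probs": {
                    str(k): v for k, v in subj.schedule.fractal_probs.items()
                },
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory: Union[str, Path]) -> list:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cohort = []
    for entry in manifest["subjects"]:
        frame = pd.read_csv(directory / f"{entry['subject_id']}.csv")
        cohort.append(
            subject_from_frame(
                frame,
                fractal_probs={
                    int(k): v for k, v in entry["fractal_probs"].items()
                },
                valence=entry["valence"],
                trait_score=entry["trait_score"],
                true_params=entry["true_params"],
            )
        )
    return cohort
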