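"""Trial records — the row type of the trial-log CSV — and block execution.

`run_staircase_block` is the inner loop shared by practice, titration and
training: present the staircase's current level, collect a simulated
response, score it, and update the staircase from the driving component.
Aborted trials are logged but leave the staircase untouched and do not count
toward the block length.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .observer import ParametricObserver
from .staircase import Staircase
from .stimulus import (
    OBLIQUE_DIRECTIONS,
    TrialStimulus,
    component_truth,
    quadrant_label,
    score_response,
)

__all__ = ["TrialRecord", "run_staircase_block", "records_to_frame"]

#: Fixed column order of the trial-log CSV.
TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "phase",
    "session_day",
    "trial_index",
    "location",
    "global_direction_deg",
    "range_level_index",
    "direction_range_deg",
    "noise_fraction",
    "staircase_id",
    "cue_present",
    "response_quadrant",
    "combined_correct",
    "h_correct",
    "v_correct",
    "aborted",
    "rng_seed_tag",
]


@dataclass
class TrialRecord:
    """One row of the trial log.

    Correctness fields are ``None`` on aborted trials (empty cells in the
    CSV); ``cue_present`` may only be true for AV-group training trials.
    """

    participant_id: str = ""
    group: str = ""
    phase: str = ""
    session_day: int = 0
    trial_index: int = 0
    location: str = "trained"
    global_direction_deg: int = 45
    range_level_index: int = 0
    direction_range_deg: float = 0.0
    noise_fraction: float = 0.0
    staircase_id: str = "V"
    cue_present: bool = False
    response_quadrant: str | None = None
    combined_correct: bool | None = None
    h_correct: bool | None = None
    v_correct: bool | None = None
    aborted: bool = False
    rng_seed_tag: str = ""

    def __post_init__(self) -> None:
        if self.cue_present and not (self.group == "AV" and self.phase == "training"):
            raise ValueError("the auditory cue occurs only in AV-group training")
        if self.phase == "posttest" and self.cue_present:
            raise ValueError("no auditory cue during post-tests")


def run_staircase_block(
    observer: ParametricObserver,
    noise_fraction: float,
    staircase: Staircase,
    n_trials: int,
    rng: np.random.Generator,
    session_day: int = 1,
    cue_present: bool = False,
    location: str = "trained",
    phase: str = "",
    group: str = "",
    level_grid: np.ndarray | None = None,
    start_trial_index: int = 0,
    max_attempts_factor: int = 50,
) -> list[TrialRecord]:
    """Run one single-staircase block of ``n_trials`` completed trials.

    The global direction is drawn i.i.d. uniform over the four obliques each
    trial; the staircase is updated from the correctness of its driving
    component.  Returns the per-trial records (completed and aborted);
    participant metadata on the records is left blank for the caller to fill.
    """
    levels = staircase.levels if level_grid is None else np.asarray(level_grid, float)
    records: list[TrialRecord] = []
    completed = 0
    trial_index = start_trial_index
    attempts = 0
    while completed < n_trials:
        attempts += 1
        if attempts > max_attempts_factor * n_trials:
            raise RuntimeError("abort rate too high to complete the block")
        direction = int(rng.choice(OBLIQUE_DIRECTIONS))
        level = staircase.level_index
        trial = TrialStimulus.from_level(
            direction, level, noise_fraction, location, levels
        )
        report = observer.respond(trial, session_day, rng, cue_present=cue_present)
        base = dict(
            phase=phase,
            group=group,
            session_day=session_day,
            trial_index=trial_index,
            location=location,
            global_direction_deg=direction,
            range_level_index=level,
            direction_range_deg=float(levels[level]),
            noise_fraction=noise_fraction,
            staircase_id="V" if staircase.state.driving_component == "vertical" else "H",
            cue_present=cue_present,
        )
        if report.aborted:
            staircase.abort()
            records.append(TrialRecord(aborted=True, **base))
        else:
            truth = component_truth(direction)
            combined, h_ok, v_ok = score_response(truth, report.response)
            driving = v_ok if staircase.state.driving_component == "vertical" else h_ok
            staircase.update(driving)
            records.append(
                TrialRecord(
                    response_quadrant=quadrant_label(report.response),
                    combined_correct=combined,
                    h_correct=h_ok,
                    v_correct=v_ok,
                    aborted=False,
                    **base,
                )
            )
            completed += 1
        trial_index += 1
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Stack trial records into a DataFrame with the canonical column order."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df[TRIAL_COLUMNS]
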