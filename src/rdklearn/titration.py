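"""Day-1 difficulty calibration: coarse practice adjustment and fine titration.

Every participant starts the study with the noise-dot fraction set so that
their baseline direction-range threshold lies in a common band.  The
procedure has two stages:

1. *Practice*: 20-trial mini-blocks starting at 30% noise dots.  If the
   block's staircase cannot sustain a direction range of at least 80 deg the
   noise fraction drops by 10 points; if every trial is correct it rises by
   10 points; otherwise the setting is kept.
2. *Titration*: a 100-trial staircased block is fit with the Weibull and its
   DRT computed.  A DRT inside [100, 200] deg keeps the setting; above 200
   adds 5 points of noise, below 100 removes 5; at most one such fine
   adjustment is applied and the experiment proceeds.

No auditory cue is ever presented during this day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import ParametricObserver
from .psychometric import aggregate, fit_weibull
from .records import TrialRecord, records_to_frame, run_staircase_block
from .staircase import Staircase
from .stimulus import LEVEL_GRID

__all__ = ["PracticeResult", "TitrationResult", "practice_block", "titrate"]

#: Acceptance band (deg) for the titration DRT.
DRT_BAND = (100.0, 200.0)


@dataclass
class PracticeResult:
    """Outcome of the coarse practice-stage noise adjustment."""

    noise_fraction: float
    adjustments: list = field(default_factory=list)  # signed +-0.10 steps
    titratable: bool = True
    records: list = field(default_factory=list)


@dataclass
class TitrationResult:
    """Outcome of the 100-trial fine titration."""

    final_noise_fraction: float
    practice_adjustments: list = field(default_factory=list)
    fine_adjustments: list = field(default_factory=list)
    titration_drt_deg: float = float("nan")
    in_range: bool = False
    accepted: bool = False
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_noise_fraction <= 1.0:
            raise ValueError("final_noise_fraction must be in [0, 1]")


def practice_block(
    observer: ParametricObserver,
    rng: np.random.Generator,
    start_noise: float = 0.30,
    n_trials: int = 20,
    sustain_range_deg: float = 80.0,
    start_level_index: int = 2,
    max_blocks: int = 10,
    level_grid: np.ndarray = LEVEL_GRID,
) -> PracticeResult:
    """Coarse +-10% noise adjustment over 20-trial practice mini-blocks.

    The criterion "maintain a direction range threshold of at least 80 deg
    within the first 20 trials" is read as: the running staircase ends the
    mini-block at a level of at least ``sustain_range_deg``.  A block with
    every trial correct raises the noise fraction instead.  Gives up
    (``titratable=False``) after ``max_blocks`` mini-blocks.
    """
    noise = round(start_noise, 3)
    adjustments: list[float] = []
    records: list[TrialRecord] = []
    for _ in range(max_blocks):
        sc = Staircase(level_grid, start_level_index, "vertical")
        block = run_staircase_block(
            observer, noise, sc, n_trials, rng, session_day=1
        )
        records.extend(block)
        all_correct = all(
            r.v_correct for r in block if not r.aborted
        )
        sustained = sc.current_range_deg >= sustain_range_deg
        if all_correct and noise < 1.0:
            step = +0.10
        elif not sustained and noise > 0.0:
            step = -0.10
        else:
            if sustained:
                return PracticeResult(noise, adjustments, True, records)
            # already at 0% noise and still failing: not titratable
            return PracticeResult(noise, adjustments, False, records)
        adjustments.append(step)
        noise = round(min(1.0, max(0.0, noise + step)), 3)
    return PracticeResult(noise, adjustments, False, records)


def titrate(
    observer: ParametricObserver,
    noise_fraction: float,
    rng: np.random.Generator,
    n_trials: int = 100,
    start_level_index: int = 2,
    level_grid: np.ndarray = LEVEL_GRID,
    gamma: float = 0.5,
    lapse: float = 0.05,
    practice_adjustments: list | None = None,
) -> TitrationResult:
    """100-trial staircased titration block fixing the final noise fraction.

    Fits the Weibull to the vertical-component correctness of the block and
    evaluates its DRT: inside [100, 200] deg the setting is kept; otherwise
    a single +-5 point noise adjustment is applied and the experiment
    proceeds.  A non-converged fit is reported with ``accepted=False``.
    """
    sc = Staircase(level_grid, start_level_index, "vertical")
    block = run_staircase_block(
        observer, noise_fraction, sc, n_trials, rng, session_day=1
    )
    counts = aggregate(records_to_frame(block), "vertical")
    fit = fit_weibull(counts, gamma=gamma, lapse=lapse)
    result = TitrationResult(
        final_noise_fraction=round(noise_fraction, 3),
        practice_adjustments=list(practice_adjustments or []),
        records=block,
    )
    if not fit.converged:
        return result
    result.titration_drt_deg = fit.drt_deg
    lo, hi = DRT_BAND
    if lo <= fit.drt_deg <= hi:
        result.in_range = True
    elif fit.drt_deg > hi:
        result.fine_adjustments.append(+0.05)
    else:
        result.fine_adjustments.append(-0.05)
    result.final_noise_fraction = round(
        min(1.0, max(0.0, noise_fraction + sum(result.fine_adjustments))), 3
    )
    result.accepted = True
    return result
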