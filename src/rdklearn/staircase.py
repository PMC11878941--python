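"""Adaptive difficulty controllers.

The training controller is a 2-up-1-down staircase on the discrete
direction-range grid: two consecutive correct responses at a level step the
task harder (one level up), a single error steps it easier.  The rule
converges where p(correct)**2 = 1/2, i.e. p ~ 0.707.  The post-test uses two
such staircases with interleaved trials, one driven by the horizontal
component judgment and one by the vertical.  Aborted trials leave a
staircase exactly as it was ("reset to the conditions at the end of the
previous trial").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psychometric import psychometric_p
from .stimulus import LEVEL_GRID

__all__ = [
    "StaircaseState",
    "Staircase",
    "DualStaircase",
    "update_2up1down",
    "handle_abort",
    "convergence_target",
    "simulate_staircase_convergence",
]


@dataclass
class StaircaseState:
    """Current state of one up-down staircase."""

    level_index: int = 0
    streak: int = 0
    history: list = field(default_factory=list)  # (level_index, correct) pairs
    driving_component: str = "vertical"

    def __post_init__(self) -> None:
        if self.streak not in (0, 1):
            raise ValueError("streak must be 0 or 1")
        if self.driving_component not in ("vertical", "horizontal"):
            raise ValueError(f"unknown driving component {self.driving_component!r}")


def update_2up1down(
    state: StaircaseState, correct: bool, n_levels: int = len(LEVEL_GRID)
) -> StaircaseState:
    """One 2-up-1-down update; pure (returns a new state).

    Two consecutive correct responses at the same level move one level up
    (harder); any error moves one level down (easier); levels clamp to
    [0, n_levels - 1]; every level change resets the streak.
    """
    if not 0 <= state.level_index < n_levels:
        raise ValueError("level_index outside the grid")
    history = state.history + [(state.level_index, bool(correct))]
    if correct:
        if state.streak >= 1:
            level = min(state.level_index + 1, n_levels - 1)
            return StaircaseState(level, 0, history, state.driving_component)
        return StaircaseState(state.level_index, 1, history, state.driving_component)
    level = max(state.level_index - 1, 0)
    return StaircaseState(level, 0, history, state.driving_component)


def handle_abort(state: StaircaseState) -> StaircaseState:
    """An aborted trial contributes nothing: the state is returned unchanged."""
    return state


def convergence_target(n_up: int = 2) -> float:
    """Probability-correct at which an n-up-1-down staircase converges: 2**(-1/n)."""
    if n_up < 1:
        raise ValueError("n_up must be >= 1")
    return 2.0 ** (-1.0 / n_up)


class Staircase:
    """Mutable 2-up-1-down controller bound to a direction-range level grid."""

    def __init__(
        self,
        levels: np.ndarray = LEVEL_GRID,
        start_index: int = 2,
        driving_component: str = "vertical",
    ):
        self.levels = np.asarray(levels, dtype=float)
        if not 0 <= start_index < len(self.levels):
            raise ValueError("start_index outside the level grid")
        self.state = StaircaseState(start_index, 0, [], driving_component)

    @property
    def level_index(self) -> int:
        return self.state.level_index

    @property
    def current_range_deg(self) -> float:
        return float(self.levels[self.state.level_index])

    @property
    def history(self) -> list:
        return self.state.history

    def update(self, correct: bool) -> None:
        self.state = update_2up1down(self.state, correct, n_levels=len(self.levels))

    def abort(self) -> None:
        self.state = handle_abort(self.state)


class DualStaircase:
    """Two interleaved staircases, one per component judgment (post-test).

    Trials alternate strictly H, V, H, V, ... by default; with
    ``interleave="random"`` the assignment of each upcoming trial is drawn
    from the rng.  Exactly one staircase consumes each completed trial, and
    an abort leaves both staircases and the pending assignment unchanged.
    """

    def __init__(
        self,
        levels: np.ndarray = LEVEL_GRID,
        start_index_h: int = 2,
        start_index_v: int = 2,
        interleave: str = "alternate",
        rng: np.random.Generator | None = None,
    ):
        if interleave not in ("alternate", "random"):
            raise ValueError(f"unknown interleave mode {interleave!r}")
        if interleave == "random" and rng is None:
            raise ValueError("random interleave requires an rng")
        self.staircases = {
            "H": Staircase(levels, start_index_h, "horizontal"),
            "V": Staircase(levels, start_index_v, "vertical"),
        }
        self.interleave = interleave
        self._rng = rng
        self._next: str = "H"
        if interleave == "random":
            self._next = "H" if rng.random() < 0.5 else "V"

    def next_assignment(self) -> tuple[str, int]:
        """Staircase id and level index for the upcoming trial."""
        return self._next, self.staircases[self._next].level_index

    def update(self, staircase_id: str, correct: bool) -> None:
        """Consume a completed trial with the assigned component's correctness."""
        if staircase_id != self._next:
            raise ValueError(
                f"trial assigned to {self._next!r}, got update for {staircase_id!r}"
            )
        self.staircases[staircase_id].update(correct)
        if self.interleave == "alternate":
            self._next = "V" if self._next == "H" else "H"
        else:
            self._next = "H" if self._rng.random() < 0.5 else "V"

    def abort(self) -> None:
        """Aborted trial: no staircase update, assignment unchanged."""


def simulate_staircase_convergence(
    alpha: float = 160.0,
    beta: float = 2.0,
    gamma: float = 0.5,
    lapse: float = 0.0,
    levels: np.ndarray | None = None,
    n_trials: int = 20_000,
    burn_in: int = 1_000,
    start_index: int = 0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Long-run mean probability-correct visited by the 2-up-1-down rule.

    Drives the controller with a Weibull observer of known psychometric
    function and averages the observer's *analytic* probability-correct at
    the level presented on each post-burn-in trial.  For an ideal 2-up-1-down
    rule this converges to 2**(-1/2) ~ 0.707; a fine level grid (default
    5 deg steps) keeps step-size bias small.
    """
    if levels is None:
        levels = np.arange(0.0, 356.0, 5.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_by_level = psychometric_p(levels, alpha, beta, gamma, lapse)
    sc = Staircase(levels, start_index)
    total = 0.0
    for t in range(burn_in + n_trials):
        p = p_by_level[sc.level_index]
        if t >= burn_in:
            total += p
        sc.update(rng.random() < p)
    return total / n_trials
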