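"""Direction-range random-dot stimulus: parameters, dot-direction sampling, scoring.

The stimulus is a random-dot kinematogram whose difficulty is controlled by
two knobs: the *direction range* R — signal-dot directions are drawn
uniformly from [theta - R/2, theta + R/2] around the global direction theta
— and the *noise fraction* — the proportion of dots whose directions are
drawn uniformly from the full circle.  The global direction is always one
of the four obliques (45, 135, 225, 315 deg; 0 deg = rightward,
counter-clockwise positive), so every response decomposes into independent
horizontal (left/right) and vertical (up/down) component judgments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEVEL_GRID",
    "OBLIQUE_DIRECTIONS",
    "StimulusSpec",
    "TrialStimulus",
    "ComponentTruth",
    "dot_count",
    "sample_dot_directions",
    "component_truth",
    "quadrant_direction",
    "quadrant_label",
    "score_response",
]

#: The 10 discrete direction-range levels (deg) used by the staircases.
LEVEL_GRID = np.array([0, 40, 80, 120, 160, 200, 240, 280, 320, 355], dtype=float)

#: The four oblique global-motion directions (deg).
OBLIQUE_DIRECTIONS = (45, 135, 225, 315)


@dataclass(frozen=True)
class StimulusSpec:
    """Physical parameters of the random-dot stimulus.

    Defaults describe a 5 deg aperture at 3.5 dots/deg^2, 14 arcmin dots
    moving at 10 deg/s with a 250 ms lifetime, shown for 500 ms at 90 Hz.
    """

    aperture_diameter_deg: float = 5.0
    dot_diameter_arcmin: float = 14.0
    dot_density_per_deg2: float = 3.5
    dot_speed_deg_per_s: float = 10.0
    dot_lifetime_ms: float = 250.0
    duration_ms: float = 500.0
    frame_rate_hz: float = 90.0

    def __post_init__(self) -> None:
        for name in (
            "aperture_diameter_deg",
            "dot_diameter_arcmin",
            "dot_density_per_deg2",
            "dot_speed_deg_per_s",
            "dot_lifetime_ms",
            "duration_ms",
            "frame_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration_ms < self.dot_lifetime_ms:
            raise ValueError("duration_ms must be >= dot_lifetime_ms")

    @property
    def samples_per_slot(self) -> int:
        """Independent direction draws per dot slot (one per lifetime)."""
        return max(1, round(self.duration_ms / self.dot_lifetime_ms))


@dataclass(frozen=True)
class TrialStimulus:
    """One stimulus presentation."""

    global_direction_deg: int
    range_level_index: int
    direction_range_deg: float
    noise_fraction: float
    location: str = "trained"
    level_grid: np.ndarray = field(default_factory=lambda: LEVEL_GRID, repr=False)

    def __post_init__(self) -> None:
        if self.global_direction_deg not in OBLIQUE_DIRECTIONS:
            raise ValueError(
                f"global_direction_deg must be oblique, got {self.global_direction_deg}"
            )
        if not 0 <= self.range_level_index < len(self.level_grid):
            raise ValueError(f"range_level_index {self.range_level_index} out of grid")
        if not math.isclose(
            self.direction_range_deg, float(self.level_grid[self.range_level_index])
        ):
            raise ValueError("direction_range_deg inconsistent with range_level_index")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.location not in ("trained", "untrained"):
            raise ValueError(f"unknown location {self.location!r}")

    @classmethod
    def from_level(
        cls,
        global_direction_deg: int,
        range_level_index: int,
        noise_fraction: float,
        location: str = "trained",
        level_grid: np.ndarray = LEVEL_GRID,
    ) -> "TrialStimulus":
        return cls(
            global_direction_deg,
            range_level_index,
            float(level_grid[range_level_index]),
            noise_fraction,
            location,
            level_grid,
        )


@dataclass(frozen=True)
class ComponentTruth:
    """Horizontal and vertical poles of an oblique direction (or a response)."""

    horizontal: str  # "left" | "right"
    vertical: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.horizontal not in ("left", "right"):
            raise ValueError(f"horizontal must be left/right, got {self.horizontal!r}")
        if self.vertical not in ("up", "down"):
            raise ValueError(f"vertical must be up/down, got {self.vertical!r}")


_QUADRANTS = {
    45: ComponentTruth("right", "up"),
    135: ComponentTruth("left", "up"),
    225: ComponentTruth("left", "down"),
    315: ComponentTruth("right", "down"),
}
_DIRECTION_OF = {v: k for k, v in _QUADRANTS.items()}


def dot_count(spec: StimulusSpec) -> int:
    """Number of dots in the aperture: round(density * aperture area)."""
    area = math.pi * (spec.aperture_diameter_deg / 2.0) ** 2
    return round(spec.dot_density_per_deg2 * area)


def component_truth(global_direction_deg: int) -> ComponentTruth:
    """Decompose an oblique direction into its horizontal/vertical poles."""
    try:
        return _QUADRANTS[global_direction_deg]
    except KeyError:
        raise ValueError(
            f"global direction must be one of {OBLIQUE_DIRECTIONS}, "
            f"got {global_direction_deg}"
        ) from None


def quadrant_direction(truth: ComponentTruth) -> int:
    """The oblique direction (deg) whose decomposition is ``truth``."""
    return _DIRECTION_OF[truth]


def quadrant_label(truth: ComponentTruth) -> str:
    """Human-readable quadrant name, e.g. ``upper_right``."""
    return f"{'upper' if truth.vertical == 'up' else 'lower'}_{truth.horizontal}"


def score_response(
    truth: ComponentTruth, response: ComponentTruth
) -> tuple[bool, bool, bool]:
    """Score a 4AFC quadrant response against the true direction.

    Returns ``(combined_correct, horizontal_correct, vertical_correct)``;
    the combined judgment is correct exactly when both components are.
    """
    h = truth.horizontal == response.horizontal
    v = truth.vertical == response.vertical
    return (h and v, h, v)


def sample_dot_directions(
    spec: StimulusSpec,
    trial: TrialStimulus,
    rng: np.random.Generator,
    fixed_noise_count: bool = False,
) -> np.ndarray:
    """Sample the dot-direction realizations (deg, in [0, 360)) for one trial.

    Each of the ``dot_count(spec)`` dot slots contributes
    ``spec.samples_per_slot`` independent draws (a respawn re-draws both the
    direction and the signal/noise identity).  Noise draws are uniform on the
    circle; signal draws are uniform on the closed interval
    [theta - R/2, theta + R/2], wrapped modulo 360.

    With ``fixed_noise_count`` the number of noise draws is exactly
    ``round(noise_fraction * n)`` instead of per-draw Bernoulli.
    """
    if not 0.0 <= trial.noise_fraction <= 1.0:
        raise ValueError("noise_fraction must be in [0, 1]")
    n = dot_count(spec) * spec.samples_per_slot
    if n == 0:
        return np.empty(0)
    if fixed_noise_count:
        k = round(trial.noise_fraction * n)
        is_noise = np.zeros(n, dtype=bool)
        is_noise[rng.choice(n, size=k, replace=False)] = True
    else:
        is_noise = rng.random(n) < trial.noise_fraction
    theta = float(trial.global_direction_deg)
    half = trial.direction_range_deg / 2.0
    directions = np.where(
        is_noise,
        rng.uniform(0.0, 360.0, size=n),
        rng.uniform(theta - half, theta + half, size=n),
    )
    return np.mod(directions, 360.0)
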