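"""Run configuration: protocol sizes, level grid, and observer populations.

The defaults reproduce the study conditions: a titration day, ten training
sessions of 300 trials, and a cue-free post-test of 200 trials at each of
the trained and untrained locations, for a cohort of 8 visual-only (V) and
9 audio-visual (AV) simulated participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .stimulus import LEVEL_GRID, StimulusSpec

__all__ = ["GroupConfig", "ProtocolConfig"]


@dataclass
class GroupConfig:
    """An observer population: group label, size, and parameter means/SDs.

    Between-participant variation is Gaussian around the means, truncated to
    the valid parameter ranges.  The AV group trains with the auditory cue
    (informative about the horizontal component only); its horizontal
    learning is faster but, by default, does not transfer to the untrained
    location (``transfer_h = 0``).
    """

    label: str = "V"
    size: int = 8
    alpha_mean: float = 260.0
    alpha_sd: float = 50.0
    beta: float = 2.0
    lapse: float = 0.05
    learn_rate_v_mean: float = 9.5
    learn_rate_v_sd: float = 2.0
    learn_rate_h_mean: float = 9.5
    learn_rate_h_sd: float = 2.0
    transfer_h: float = 1.0
    transfer_v: float = 1.0
    av_cue: bool = False
    cue_reliability: float | None = None
    abort_prob: float = 0.0
    noise_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        if self.label not in ("V", "AV"):
            raise ValueError("group label must be 'V' or 'AV'")


def _default_groups() -> list[GroupConfig]:
    return [
        GroupConfig(label="V", size=8),
        GroupConfig(
            label="AV",
            size=9,
            learn_rate_v_mean=6.0,
            learn_rate_h_mean=12.0,
            learn_rate_h_sd=3.0,
            transfer_h=0.0,
            av_cue=True,
        ),
    ]


@dataclass
class ProtocolConfig:
    """Full protocol description for a simulated cohort run."""

    trials_per_training_session: int = 300
    training_days: int = 10
    posttest_trials_per_location: int = 200
    start_level_index: int = 2
    carry_over_staircase: bool = True
    posttest_interleave: str = "alternate"
    practice_start_noise: float = 0.30
    level_grid: list = field(default_factory=lambda: LEVEL_GRID.tolist())
    master_seed: int = 0
    groups: list = field(default_factory=_default_groups)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def __post_init__(self) -> None:
        for name in (
            "trials_per_training_session",
            "training_days",
            "posttest_trials_per_location",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        grid = np.asarray(self.level_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("level_grid must be strictly increasing with >= 2 levels")
        if not 0 <= self.start_level_index < len(grid):
            raise ValueError("start_level_index outside the level grid")

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.level_grid, dtype=float)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["groups"] = [asdict(g) for g in self.groups]
        payload["stimulus"] = asdict(self.stimulus)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "groups" in payload:
            payload["groups"] = [GroupConfig(**g) for g in payload["groups"]]
        if "stimulus" in payload:
            payload["stimulus"] = StimulusSpec(**payload["stimulus"])
        return cls(**payload)
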