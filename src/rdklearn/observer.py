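"""Simulated observers for the 4AFC direction-range task.

Two observers are provided:

* :class:`ParametricObserver` answers each component judgment by a Bernoulli
  draw from an explicit Weibull psychometric function, so its ground truth is
  exactly invertible — the workhorse for parameter-recovery tests.  Learning
  enters as a linear increase of the Weibull scale alpha per training
  session; at the untrained location only a configurable fraction of the
  accumulated learning is expressed (retinotopic transfer).  Noise dots make
  the task harder by shrinking alpha: alpha_eff = alpha * (1 - nu)**c.
* :class:`MechanisticObserver` pools the actual dot-direction samples
  (circular mean) and adds von Mises internal noise, answering with the
  quadrant containing the perceived direction — used to check that the
  Weibull functional form is an adequate description of such a mechanism.

During audio-visual training the auditory cue is informative only about the
horizontal motion component; a cued observer answers the horizontal judgment
from the cue with probability ``cue_reliability`` (default 1 - lapse, so
lapses still occur on cued trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psychometric import psychometric_p
from .stimulus import ComponentTruth, TrialStimulus, component_truth

__all__ = [
    "ObserverParams",
    "PerceptReport",
    "ParametricObserver",
    "MechanisticObserver",
    "psychometric_p",
    "respond_parametric",
    "respond_mechanistic",
]

_OPPOSITE = {"left": "right", "right": "left", "up": "down", "down": "up"}


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth parameters of a simulated participant.

    alpha_*_deg are Weibull scales in direction-range degrees at zero noise;
    learn_rate_* are degrees of alpha added per completed training session;
    transfer_* is the fraction of accumulated learning expressed at the
    untrained location; cue_reliability is the probability that the auditory
    cue yields the correct horizontal response when present (None means
    1 - lapse); noise_exponent is c in alpha_eff = alpha * (1 - nu)**c.
    """

    alpha_h_deg: float = 260.0
    alpha_v_deg: float = 260.0
    beta: float = 2.0
    lapse: float = 0.05
    chance: float = 0.5
    learn_rate_h: float = 0.0
    learn_rate_v: float = 0.0
    transfer_h: float = 1.0
    transfer_v: float = 1.0
    av_cue: bool = False
    cue_reliability: float | None = None
    abort_prob: float = 0.0
    noise_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_h_deg <= 0 or self.alpha_v_deg <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be strictly positive")
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError("lapse must be in [0, 0.2]")
        for name in ("chance", "transfer_h", "transfer_v", "abort_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cue_reliability is not None and not 0.0 <= self.cue_reliability <= 1.0:
            raise ValueError("cue_reliability must be in [0, 1]")

    @property
    def effective_cue_reliability(self) -> float:
        return 1.0 - self.lapse if self.cue_reliability is None else self.cue_reliability

    def effective_alpha(
        self, component: str, session_day: int, location: str, noise_fraction: float
    ) -> float:
        """Weibull scale after learning, transfer and noise attenuation."""
        if component == "h":
            base, rate, transfer = self.alpha_h_deg, self.learn_rate_h, self.transfer_h
        elif component == "v":
            base, rate, transfer = self.alpha_v_deg, self.learn_rate_v, self.transfer_v
        else:
            raise ValueError(f"component must be 'h' or 'v', got {component!r}")
        accrued = rate * max(0, session_day - 1)
        if location == "untrained":
            accrued *= transfer
        # floor keeps psi well-defined at 100% noise (performance -> chance)
        alpha = (base + accrued) * (1.0 - noise_fraction) ** self.noise_exponent
        return max(alpha, 1e-9)


@dataclass(frozen=True)
class PerceptReport:
    """Outcome of one simulated trial: a quadrant response, or an abort."""

    response: ComponentTruth | None
    aborted: bool = False

    def __post_init__(self) -> None:
        if self.aborted and self.response is not None:
            raise ValueError("aborted trials carry no response")
        if not self.aborted and self.response is None:
            raise ValueError("completed trials must carry a response")


def respond_parametric(
    obs: ObserverParams,
    trial: TrialStimulus,
    session_day: int,
    rng: np.random.Generator,
    cue_present: bool = False,
) -> PerceptReport:
    """Simulate one 4AFC response from the parametric observer.

    Component correctness is Bernoulli with probability given by the Weibull
    psychometric function at the trial's direction range (horizontal:
    ``cue_reliability`` instead, when the observer is cued).  An incorrect
    component picks the opposite pole of that axis.  The trial aborts
    (fixation/head break) with probability ``abort_prob`` before responding.
    """
    if session_day < 1:
        raise ValueError("session_day must be >= 1")
    if obs.abort_prob > 0 and rng.random() < obs.abort_prob:
        return PerceptReport(None, aborted=True)
    truth = component_truth(trial.global_direction_deg)
    r = trial.direction_range_deg

    alpha_v = obs.effective_alpha("v", session_day, trial.location, trial.noise_fraction)
    p_v = psychometric_p(r, alpha_v, obs.beta, obs.chance, obs.lapse)
    v_ok = rng.random() < p_v

    if obs.av_cue and cue_present:
        h_ok = rng.random() < obs.effective_cue_reliability
    else:
        alpha_h = obs.effective_alpha(
            "h", session_day, trial.location, trial.noise_fraction
        )
        p_h = psychometric_p(r, alpha_h, obs.beta, obs.chance, obs.lapse)
        h_ok = rng.random() < p_h

    response = ComponentTruth(
        truth.horizontal if h_ok else _OPPOSITE[truth.horizontal],
        truth.vertical if v_ok else _OPPOSITE[truth.vertical],
    )
    return PerceptReport(response)


def respond_mechanistic(
    kappa: float,
    dot_directions_deg: np.ndarray,
    rng: np.random.Generator,
    abort_prob: float = 0.0,
) -> PerceptReport:
    """Vector-pooling observer: circular mean of the dots plus von Mises noise.

    The response is the quadrant containing the perceived direction; exact
    quadrant-boundary ties are broken by the rng.
    """
    dirs = np.asarray(dot_directions_deg, dtype=float)
    if dirs.size == 0:
        raise ValueError("dot_directions_deg must be non-empty")
    if abort_prob > 0 and rng.random() < abort_prob:
        return PerceptReport(None, aborted=True)
    rad = np.deg2rad(dirs)
    mean_dir = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    perceived = mean_dir + rng.vonmises(0.0, kappa)
    c, s = np.cos(perceived), np.sin(perceived)
    if c == 0.0:
        c = rng.choice([-1.0, 1.0])
    if s == 0.0:
        s = rng.choice([-1.0, 1.0])
    return PerceptReport(
        ComponentTruth("right" if c > 0 else "left", "up" if s > 0 else "down")
    )


class ParametricObserver:
    """Stateful wrapper pairing :class:`ObserverParams` with a noise setting."""

    def __init__(self, params: ObserverParams, noise_fraction: float | None = None):
        self.params = params
        self.noise_fraction = noise_fraction

    def with_noise(self, noise_fraction: float) -> "ParametricObserver":
        return ParametricObserver(self.params, noise_fraction)

    def respond(
        self,
        trial: TrialStimulus,
        session_day: int,
        rng: np.random.Generator,
        cue_present: bool = False,
    ) -> PerceptReport:
        return respond_parametric(self.params, trial, session_day, rng, cue_present)

    def p_correct(
        self,
        component: str,
        range_deg: float,
        session_day: int = 1,
        location: str = "trained",
        noise_fraction: float | None = None,
    ) -> float:
        """Analytic probability-correct for one component (the ground truth)."""
        nu = self.noise_fraction if noise_fraction is None else noise_fraction
        nu = 0.0 if nu is None else nu
        alpha = self.params.effective_alpha(component, session_day, location, nu)
        return psychometric_p(
            range_deg, alpha, self.params.beta, self.params.chance, self.params.lapse
        )


class MechanisticObserver:
    """Vector-pooling observer with von Mises internal direction noise."""

    def __init__(self, kappa: float = 8.0, abort_prob: float = 0.0):
        if kappa <= 0:
            raise ValueError("kappa must be strictly positive")
        self.kappa = kappa
        self.abort_prob = abort_prob

    def respond(
        self, dot_directions_deg: np.ndarray, rng: np.random.Generator
    ) -> PerceptReport:
        return respond_mechanistic(self.kappa, dot_directions_deg, rng, self.abort_prob)
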