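"""Episodic two-alternative decision environment.

At every time step the agent sees one observation (a flattened frame) and
picks one of three actions: request an extra observation, or commit to class
1 or class 2.  Rewards:

- committing to the correct class after stimulus onset: ``+1``;
- committing to the wrong class after onset: ``0``;
- committing before onset (during fixation): ``0``, trial ends — there is
  no right answer yet;
- each extra observation costs ``observation_cost`` (0 by default, negative
  to penalize slowness);
- if no class is chosen after ``max_steps`` time steps (counted from trial
  start, fixation included) the trial ends with reward 0.

The stimulus regime is dynamic noise by default (a fresh mask per
observation); static is available through the config.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stimuli import (
    DEFAULT_NOISE_LEVELS, ClassTemplates, NoiseSpec, Regime, apply_noise,
    make_class_templates,
)


class Action(enum.IntEnum):
    OBSERVE = 0
    CHOOSE_1 = 1
    CHOOSE_2 = 2


class Outcome(enum.Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    PREMATURE = "premature"
    TIMEOUT = "timeout"


@dataclass(frozen=True)
class StepOutcome:
    reward: float
    done: bool
    observation: np.ndarray | None     # None once the trial has ended
    t: int
    outcome: Outcome | None = None


@dataclass
class EnvConfig:
    noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS
    regime: Regime = "dynamic"
    observation_cost: float = 0.0
    max_steps: int = 50
    pre_stimulus_steps: int = 3
    correct_reward: float = 1.0
    incorrect_reward: float = 0.0
    timeout_reward: float = 0.0
    premature_reward: float = 0.0
    class_pair: tuple[int, int] = (0, 1)   # which template classes form the 2AFC
    grid: tuple[int, int] = (14, 14)
    variability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_steps < self.pre_stimulus_steps + 1:
            raise ValueError("max_steps must exceed the fixation period")


class DecisionEnv:
    """The 2AFC task as a reset/step environment.

    Observations are flattened frames; the first ``pre_stimulus_steps``
    observations of a trial are all-zero fixation frames.  The internal
    clock ``t`` counts observations delivered so far minus one (the
    observation index currently in view).
    """

    def __init__(self, config: EnvConfig, templates: ClassTemplates | None = None):
        self.config = config
        self.templates = templates if templates is not None else make_class_templates(
            max(config.class_pair) + 1, config.grid, config.variability,
            seed=config.seed + 10_000, min_separation=0.2)
        self.rng = np.random.default_rng(config.seed)
        self.n_obs = self.templates.grid[0] * self.templates.grid[1]
        self._done = True
        self.label: int | None = None          # 0 or 1 (index into class_pair)
        self.noise: NoiseSpec | None = None

    # -- trial lifecycle ----------------------------------------------------

    def reset(self, label: int | None = None, proportion: float | None = None) -> np.ndarray:
        """Start a fresh trial; returns the first (all-zero) observation."""
        cfg = self.config
        if label is None:
            label = int(self.rng.integers(2))
        if proportion is None:
            proportion = float(self.rng.choice(np.asarray(cfg.noise_levels)))
        self.label = label
        self.noise = NoiseSpec(proportion=proportion, regime=cfg.regime)
        self._base = self.templates.sample(cfg.class_pair[label], self.rng)
        if cfg.regime == "static":
            self._static_frame = apply_noise(self._base, self.noise, self.rng)
        self.t = 0
        self._done = False
        return np.zeros(self.n_obs)

    def _next_observation(self, t: int) -> np.ndarray:
        cfg = self.config
        if t < cfg.pre_stimulus_steps:
            return np.zeros(self.n_obs)
        if cfg.regime == "static":
            return self._static_frame.ravel().copy()
        return apply_noise(self._base, self.noise, self.rng).ravel()

    def step(self, action: Action | int) -> StepOutcome:
        """Advance one time step given the agent's action."""
        if self._done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        action = Action(action)
        cfg = self.config
        onset = self.t >= cfg.pre_stimulus_steps
        self.t += 1
        if action is not Action.OBSERVE:
            self._done = True
            if not onset:
                return StepOutcome(cfg.premature_reward, True, None, self.t,
                                   Outcome.PREMATURE)
            chosen = int(action) - 1
            if chosen == self.label:
                return StepOutcome(cfg.correct_reward, True, None, self.t,
                                   Outcome.CORRECT)
            return StepOutcome(cfg.incorrect_reward, True, None, self.t,
                               Outcome.INCORRECT)
        if self.t >= cfg.max_steps:
            self._done = True
            return StepOutcome(cfg.timeout_reward, True, None, self.t,
                               Outcome.TIMEOUT)
        return StepOutcome(cfg.observation_cost, False,
                           self._next_observation(self.t), self.t, None)


@dataclass
class EpisodeRecord:
    """Full log of one RL trial."""

    observations: np.ndarray          # (T+1, n_obs): obs in view at each acted step
    actions: np.ndarray               # (T+1,) int
    pis: np.ndarray                   # (T+1, 3) action probabilities
    rewards: np.ndarray               # (T+1,)
    values: np.ndarray                # (T+1,) critic estimates
    hidden_policy: np.ndarray         # (T+1, n_h)
    hidden_value: np.ndarray          # (T+1, n_h)
    label: int
    noise_proportion: float
    outcome: Outcome

    @property
    def n_steps(self) -> int:
        return len(self.rewards)

    @property
    def answered(self) -> bool:
        return self.outcome in (Outcome.CORRECT, Outcome.INCORRECT)

    @property
    def correct(self) -> bool:
        return self.outcome is Outcome.CORRECT

    @property
    def decision(self) -> int | None:
        """1 or 2 if a class was chosen, else None."""
        a = int(self.actions[-1])
        return a if a in (1, 2) else None

    def summary(self) -> dict:
        return dict(label=self.label, noise=self.noise_proportion,
                    n_steps=self.n_steps, outcome=self.outcome.value,
                    correct=self.correct, answered=self.answered,
                    total_reward=float(self.rewards.sum()))
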