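"""Advantage actor-critic training of the decision agent.

Two *separate* recurrent networks (no shared parameters) map observations to
(i) a policy — softmax probabilities over the three actions — and (ii) a
scalar value estimate of expected future reward.  With per-episode index
t = 0..T, the objective minimized over a batch of N completed episodes is

    Q = (1/N) sum_n [ -J_n + 0.5 * V_n + beta * R_n ]

where

    J_n = sum_t gamma^t rho_t                       (discounted return)
    A_t = sum_{t'>=t} [rho_t' - v(x_t')]            (advantage; optionally
                                                     discounted by gamma^(t'-t))
    V_n = (1/(T+1)) sum_t A_t^2                     (critic loss)
    R_n = sum_t sum_a pi(a|x_t) log pi(a|x_t)       (negative entropy)

The policy gradient is the REINFORCE-with-baseline estimator
``grad J_n = sum_t grad log pi(a_t|x_t) * A_t`` with the advantage treated
as a constant: the critic receives gradients only through ``V_n``.  The
entropy term (weight ``beta``, 1.0 for the literal objective) pushes action
probabilities away from 0/1 to sustain exploration.

All gradients are computed by the explicit reverse pass in
:mod:`evint.grunet`; their agreement with central finite differences of
:func:`surrogate_objective` is the most important test in the repository.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .grunet import (
    GRUParams, ReadoutParams, gru_step, init_gru, init_readout, readout,
    save_checkpoint, load_checkpoint, unroll, unroll_backward, zero_grads,
)
from .optim import Adam
from .rl_environment import Action, DecisionEnv, EnvConfig, EpisodeRecord, Outcome
from .supervised import softmax


# ---------------------------------------------------------------------------
# Objective pieces

def discounted_return(rewards: np.ndarray, gamma: float) -> float:
    """``J = sum_t gamma^t rho_t`` over one episode."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0,1], got {gamma}")
    rewards = np.asarray(rewards, dtype=np.float64)
    return float(np.sum(gamma ** np.arange(len(rewards)) * rewards))


def _discounted_tail(x: np.ndarray, gamma: float) -> np.ndarray:
    out = np.empty_like(x)
    acc = 0.0
    for t in range(len(x) - 1, -1, -1):
        acc = x[t] + gamma * acc
        out[t] = acc
    return out


def advantages(
    rewards: np.ndarray,
    values: np.ndarray,
    gamma: float | None = None,
    mode: str = "residual",
) -> np.ndarray:
    """Per-step advantage over one episode.

    ``mode="residual"`` (default): ``A_t = sum_{t'>=t} [rho_t' - v_t']`` —
    the value estimate is subtracted at every tail step.  With ``gamma``
    given the tail sum is discounted by ``gamma^(t'-t)``.

    ``mode="baseline"``: the standard REINFORCE-with-baseline form
    ``A_t = (sum_{t'>=t} gamma^(t'-t) rho_t') - v(x_t)`` — the baseline is
    subtracted once, at the step being credited.  The residual form
    systematically penalizes long trajectories once the critic is accurate
    (each extra step subtracts a full value estimate from the advantage of
    every earlier action), so training uses the baseline form by default;
    see the methods note.
    """
    rewards = np.asarray(rewards, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if rewards.shape != values.shape:
        raise ValueError("rewards and values must have equal length")
    g = 1.0 if gamma is None else gamma
    if mode == "residual":
        return _discounted_tail(rewards - values, g)
    if mode == "baseline":
        return _discounted_tail(rewards, g) - values
    raise ValueError(f"unknown advantage mode {mode!r}")


def value_baseline_loss(
    rewards: np.ndarray,
    values: np.ndarray,
    gamma: float | None = None,
    mode: str = "residual",
) -> float:
    """Critic loss ``V_n = (1/(T+1)) sum_t A_t^2`` (mean squared advantage)."""
    rewards = np.asarray(rewards, dtype=np.float64)
    if rewards.size == 0:
        raise ValueError("empty episode")
    A = advantages(rewards, values, gamma, mode=mode)
    return float(np.mean(A**2))


def entropy_regularizer(pis: np.ndarray) -> float:
    """Negative policy entropy summed over steps: ``sum_t sum_a pi log pi``.

    Convention ``0 * log 0 = 0``; minimizing this pushes the policy toward
    uniform action probabilities.
    """
    pis = np.asarray(pis, dtype=np.float64)
    if not np.allclose(pis.sum(axis=-1), 1.0) or np.any(pis < 0):
        raise ValueError("each pi must be a probability distribution")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pis > 0, pis * np.log(np.where(pis > 0, pis, 1.0)), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# Configuration / agent containers

@dataclass
class RLConfig:
    gamma: float = 0.9
    value_coef: float = 0.5
    entropy_coef: float = 1.0
    advantage_mode: str = "residual"       # "residual" (printed form) | "baseline"
    discount_advantages: bool = False
    hidden_size: int = 100
    total_steps: int = 200_000
    lr: float = 1e-3
    batch_episodes: int = 16
    seed: int = 0
    tau: float = 0.5
    tied_candidate_input: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0,1], got {self.gamma}")


@dataclass
class TrainedAgent:
    policy_gru: GRUParams
    policy_out: ReadoutParams
    value_gru: GRUParams
    value_out: ReadoutParams
    rl_config: RLConfig
    env_config: EnvConfig

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_checkpoint(d / "policy", self.policy_gru, self.policy_out)
        save_checkpoint(d / "value", self.value_gru, self.value_out)

    def policy_for(self, observations: np.ndarray) -> np.ndarray:
        """Action probabilities along a forced observation sequence."""
        _, logits, _ = unroll(self.policy_gru, self.policy_out, observations)
        return softmax(logits)


def init_agent(env: DecisionEnv, cfg: RLConfig) -> TrainedAgent:
    """Fresh agent: fan-in-initialized recurrent layers, zero-initialized
    readout heads so the initial policy is uniform and the initial value
    estimate is exactly zero (no spurious advantage before any reward has
    been seen)."""
    rng = np.random.default_rng(cfg.seed)
    n_in = env.n_obs
    kw = dict(tau=cfg.tau, tied_candidate_input=cfg.tied_candidate_input)
    policy_out = init_readout(cfg.hidden_size, 3, rng)
    value_out = init_readout(cfg.hidden_size, 1, rng)
    policy_out.W_out[:] = 0.0
    value_out.W_out[:] = 0.0
    return TrainedAgent(
        policy_gru=init_gru(n_in, cfg.hidden_size, rng, **kw),
        policy_out=policy_out,
        value_gru=init_gru(n_in, cfg.hidden_size, rng, **kw),
        value_out=value_out,
        rl_config=cfg, env_config=env.config,
    )


# ---------------------------------------------------------------------------
# Batched objective with gradients

def _episode_forward(agent: TrainedAgent, obs: np.ndarray):
    hs_p, logits, caches_p = unroll(agent.policy_gru, agent.policy_out, obs)
    hs_v, vout, caches_v = unroll(agent.value_gru, agent.value_out, obs)
    return hs_p, softmax(logits), caches_p, hs_v, vout[:, 0], caches_v


def objective(
    agent: TrainedAgent,
    episodes: Sequence[EpisodeRecord],
    cfg: RLConfig | None = None,
) -> tuple[float, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Batch objective Q and its gradients for policy and value parameters.

    The episodes must be complete (terminated).  Networks are re-run over
    the logged observations, so the returned gradients are exact for the
    current parameters regardless of which parameters generated the episode.
    """
    cfg = cfg or agent.rl_config
    if len(episodes) == 0:
        raise ValueError("need at least one episode")
    for ep in episodes:
        if ep.outcome is None:
            raise ValueError("incomplete episode in batch")
    N = len(episodes)
    gA = cfg.gamma if cfg.discount_advantages else None
    grads_p = zero_grads(agent.policy_gru, agent.policy_out)
    grads_v = zero_grads(agent.value_gru, agent.value_out)
    Q = 0.0
    for ep in episodes:
        hs_p, pi, caches_p, hs_v, v, caches_v = _episode_forward(agent, ep.observations)
        T1 = len(ep.rewards)
        A = advantages(ep.rewards, v, gA, mode=cfg.advantage_mode)
        J = discounted_return(ep.rewards, cfg.gamma)
        Vn = float(np.mean(A**2))
        Rn = entropy_regularizer(pi)
        Q += (-J + cfg.value_coef * Vn + cfg.entropy_coef * Rn) / N

        # policy logits gradient: REINFORCE term (A constant) + entropy
        onehot = np.zeros_like(pi)
        onehot[np.arange(T1), ep.actions] = 1.0
        d_logits = A[:, None] * (pi - onehot)
        g = (pi * np.log(np.clip(pi, 1e-300, None))).sum(axis=1, keepdims=True)
        d_logits += cfg.entropy_coef * pi * (np.log(np.clip(pi, 1e-300, None)) - g)
        unroll_backward(agent.policy_gru, agent.policy_out, hs_p, caches_p,
                        d_logits / N, grads_p)

        # value gradient
        if cfg.advantage_mode == "residual":
            # dV_n/dv_t' = -(2/(T+1)) sum_{t<=t'} gamma^(t'-t) A_t
            S = np.empty(T1)
            acc = 0.0
            gfwd = 1.0 if gA is None else gA
            for t in range(T1):
                acc = gfwd * acc + A[t]
                S[t] = acc
        else:
            # baseline form: v_t appears only in A_t, dV_n/dv_t = -(2/(T+1)) A_t
            S = A
        d_v = -(2.0 * cfg.value_coef / T1) * S
        unroll_backward(agent.value_gru, agent.value_out, hs_v, caches_v,
                        d_v[:, None] / N, grads_v)
    return Q, grads_p, grads_v


def surrogate_objective(
    agent: TrainedAgent,
    episodes: Sequence[EpisodeRecord],
    frozen_advantages: Sequence[np.ndarray],
    cfg: RLConfig | None = None,
) -> float:
    """Differentiable scalar whose exact gradient :func:`objective` computes.

    The policy term uses the *frozen* advantages (constants), matching the
    gradient-stopping convention; the critic term recomputes advantages from
    the live value estimates.  Used by the finite-difference oracle.
    """
    cfg = cfg or agent.rl_config
    gA = cfg.gamma if cfg.discount_advantages else None
    N = len(episodes)
    total = 0.0
    for ep, A_fixed in zip(episodes, frozen_advantages):
        _, pi, _, _, v, _ = _episode_forward(agent, ep.observations)
        T1 = len(ep.rewards)
        logpi_a = np.log(pi[np.arange(T1), ep.actions])
        policy_term = -float(np.sum(logpi_a * A_fixed))
        Vn = value_baseline_loss(ep.rewards, v, gA, mode=cfg.advantage_mode)
        Rn = entropy_regularizer(pi)
        total += (policy_term + cfg.value_coef * Vn + cfg.entropy_coef * Rn) / N
    return total


# ---------------------------------------------------------------------------
# Episode generation and training

def run_episode(
    agent: TrainedAgent,
    env: DecisionEnv,
    rng: np.random.Generator,
    label: int | None = None,
    proportion: float | None = None,
) -> EpisodeRecord:
    """Sample one trial: actions drawn from the (stochastic) policy."""
    obs = env.reset(label=label, proportion=proportion)
    h_p = np.zeros((1, agent.policy_gru.n_hidden))
    h_v = np.zeros((1, agent.value_gru.n_hidden))
    observations, actions, pis, rewards, values = [], [], [], [], []
    hp_log, hv_log = [], []
    done = False
    while not done:
        h_p, _ = gru_step(agent.policy_gru, h_p, obs[None, :])
        h_v, _ = gru_step(agent.value_gru, h_v, obs[None, :])
        pi = softmax(readout(agent.policy_out, h_p))[0]
        v = float(readout(agent.value_out, h_v)[0, 0])
        a = int(rng.choice(3, p=pi))
        out = env.step(a)
        observations.append(obs)
        actions.append(a)
        pis.append(pi)
        rewards.append(out.reward)
        values.append(v)
        hp_log.append(h_p[0].copy())
        hv_log.append(h_v[0].copy())
        done = out.done
        obs = out.observation
    return EpisodeRecord(
        observations=np.asarray(observations), actions=np.asarray(actions),
        pis=np.asarray(pis), rewards=np.asarray(rewards),
        values=np.asarray(values), hidden_policy=np.asarray(hp_log),
        hidden_value=np.asarray(hv_log), label=env.label,
        noise_proportion=env.noise.proportion, outcome=out.outcome,
    )


def train_agent(
    env_config: EnvConfig,
    rl_config: RLConfig,
    templates=None,
) -> tuple[TrainedAgent, pd.DataFrame]:
    """Train policy and value networks for ``total_steps`` environment steps.

    Parameters are updated once per batch of completed episodes.  Returns
    the trained agent and a learning-curve log with, per update: cumulative
    reward (exact sum of environment-emitted rewards), fraction of trials
    answered within the step limit, and accuracy on answered trials.
    Bit-identical across runs with the same configs and seed.
    """
    env = DecisionEnv(env_config, templates=templates)
    agent = init_agent(env, rl_config)
    rng = np.random.default_rng(rl_config.seed + 1)
    params_p = {**agent.policy_gru.arrays(), **agent.policy_out.arrays()}
    params_v = {**agent.value_gru.arrays(), **agent.value_out.arrays()}
    opt_p = Adam(lr=rl_config.lr)
    opt_v = Adam(lr=rl_config.lr)

    steps_done = 0
    cum_reward = 0.0
    batch: list[EpisodeRecord] = []
    rows = []
    n_update = 0
    while steps_done < rl_config.total_steps:
        ep = run_episode(agent, env, rng)
        steps_done += ep.n_steps
        cum_reward += float(ep.rewards.sum())
        batch.append(ep)
        if len(batch) >= rl_config.batch_episodes:
            Q, grads_p, grads_v = objective(agent, batch, rl_config)
            if not np.isfinite(Q):
                raise FloatingPointError(
                    f"objective diverged at update {n_update} ({rl_config})")
            opt_p.step(params_p, grads_p)
            opt_v.step(params_v, grads_v)
            n_update += 1
            answered = [b for b in batch if b.answered]
            rows.append(dict(
                update=n_update, env_steps=steps_done, objective=Q,
                cumulative_reward=cum_reward,
                frac_answered=len(answered) / len(batch),
                accuracy=(np.mean([b.correct for b in answered])
                          if answered else np.nan),
                mean_length=float(np.mean([b.n_steps for b in batch])),
            ))
            batch = []
    return agent, pd.DataFrame(rows)


def evaluate_agent(
    agent: TrainedAgent,
    env_config: EnvConfig,
    n_trials: int,
    seed: int = 0,
    proportions: Sequence[float] | None = None,
    templates=None,
) -> list[EpisodeRecord]:
    """Run the frozen stochastic policy for ``n_trials`` per noise level
    (or over the env's mixed levels if ``proportions`` is None)."""
    env = DecisionEnv(env_config, templates=templates)
    env.rng = np.random.default_rng(seed + 5)
    rng = np.random.default_rng(seed + 6)
    records = []
    if proportions is None:
        records.extend(run_episode(agent, env, rng) for _ in range(n_trials))
    else:
        for p in proportions:
            records.extend(
                run_episode(agent, env, rng, proportion=p) for _ in range(n_trials))
    return records


def episodes_to_frame(records: Sequence[EpisodeRecord]) -> pd.DataFrame:
    """One row per episode: label, noise, n_steps, outcome, reward."""
    return pd.DataFrame([r.summary() for r in records])
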