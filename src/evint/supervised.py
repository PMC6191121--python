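"""Supervised training of the recurrent classifier by BPTT.

The network is unrolled over a trial (fixation frames plus a fixed number of
stimulus frames, the *readout time*) and the softmax cross-entropy loss is
applied to the output of the final step only; gradients flow back through
every step.  Sweeping readout times 1-10, hidden sizes and noise levels
yields the accuracy-over-time surfaces that distinguish static from dynamic
noise: with a static mask extra steps carry no new information, while with a
dynamic mask accuracy grows with integration time, the more so the noisier
the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .grunet import (
    GRUParams, ReadoutParams, init_gru, init_readout,
    unroll, unroll_backward, zero_grads,
)
from .optim import Adam
from .stimuli import (
    DEFAULT_NOISE_LEVELS, ClassTemplates, Regime, TrialBatchSource,
    make_class_templates,
)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(z: np.ndarray, target: np.ndarray) -> float:
    """Softmax cross-entropy loss for one output vector and a one-hot target.

    ``loss = -sum_k t_k log y_k`` with ``y = softmax(z)``, max-shifted for
    numerical stability.
    """
    z = np.asarray(z, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if z.shape != target.shape:
        raise ValueError("logits and target must have equal length")
    if not (np.isclose(target.sum(), 1.0) and np.all((target == 0) | (target == 1))):
        raise ValueError("target must be one-hot")
    zs = z - z.max()
    log_y = zs - np.log(np.exp(zs).sum())
    return float(-(target * log_y).sum())


@dataclass
class SupervisedConfig:
    """One cell of the supervised sweep."""

    readout_time: int = 5                  # stimulus frames, 1..10
    hidden_size: int = 30
    noise_level: float = 0.0
    regime: Regime = "dynamic"
    n_classes: int = 10
    grid: tuple[int, int] = (28, 28)
    variability: float = 0.1
    pre_stimulus_steps: int = 3            # fixation frames prepended, not counted
    lr: float = 1e-3
    batch_size: int = 64
    n_updates: int = 5000
    n_eval_trials: int = 1000
    seed: int = 0
    tau: float = 0.5
    tied_candidate_input: bool = False

    def __post_init__(self) -> None:
        if self.readout_time < 1:
            raise ValueError("readout_time must be >= 1")


@dataclass
class TrainResult:
    gru: GRUParams
    out: ReadoutParams
    accuracy: float
    n_eval: int
    config: SupervisedConfig
    loss_curve: np.ndarray = field(repr=False, default=None)


def _batch_arrays(trials, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials into (T, B, n_in) inputs and (B, K) one-hot targets."""
    X = np.stack([t.flat() for t in trials], axis=1)
    Y = np.zeros((len(trials), n_classes))
    for i, t in enumerate(trials):
        Y[i, t.label] = 1.0
    return X, Y


def train_supervised(
    config: SupervisedConfig,
    templates: ClassTemplates | None = None,
) -> TrainResult:
    """Train one network at one (noise, readout time, size) cell.

    The loss is evaluated at the final unrolled step only; held-out accuracy
    is measured on ``n_eval_trials`` fresh trials.  Fully deterministic given
    the config seed.
    """
    rng = np.random.default_rng(config.seed)
    if templates is None:
        templates = make_class_templates(
            config.n_classes, config.grid, config.variability,
            seed=config.seed + 10_000)
    n_in = templates.grid[0] * templates.grid[1]
    gru = init_gru(n_in, config.hidden_size, rng, tau=config.tau,
                   tied_candidate_input=config.tied_candidate_input)
    out = init_readout(config.hidden_size, config.n_classes, rng)
    params = {**gru.arrays(), **out.arrays()}
    opt = Adam(lr=config.lr)
    source = TrialBatchSource(
        templates=templates, noise_levels=[config.noise_level],
        regime=config.regime, n_stimulus_frames=config.readout_time,
        pre_stimulus_steps=config.pre_stimulus_steps, rng=rng)

    losses = np.empty(config.n_updates)
    for step in range(config.n_updates):
        trials = source.draw_batch(config.batch_size)
        X, Y = _batch_arrays(trials, config.n_classes)
        hs, outs, caches = unroll(gru, out, X)
        y = softmax(outs[-1])
        loss = float(-np.sum(Y * np.log(np.clip(y, 1e-300, None))) / len(trials))
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at update {step}: {config}")
        losses[step] = loss
        d_outs = np.zeros_like(outs)
        d_outs[-1] = (y - Y) / len(trials)   # loss at final step only
        grads = zero_grads(gru, out)
        unroll_backward(gru, out, hs, caches, d_outs, grads)
        opt.step(params, grads)

    acc, n_eval = evaluate(gru, out, source, config.n_eval_trials)
    return TrainResult(gru=gru, out=out, accuracy=acc, n_eval=n_eval,
                       config=config, loss_curve=losses)


def evaluate(
    gru: GRUParams, out: ReadoutParams, source: TrialBatchSource, n_trials: int
) -> tuple[float, int]:
    """Held-out classification accuracy at the final step."""
    correct = 0
    chunk = 200
    done = 0
    while done < n_trials:
        trials = source.draw_batch(min(chunk, n_trials - done))
        X, _ = _batch_arrays(trials, source.templates.n_classes)
        _, outs, _ = unroll(gru, out, X)
        pred = outs[-1].argmax(axis=1)
        correct += int(sum(p == t.label for p, t in zip(pred, trials)))
        done += len(trials)
    return correct / n_trials, n_trials


def sweep_depths(
    base: SupervisedConfig,
    readout_times: Sequence[int] = range(1, 11),
    noise_levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
    hidden_sizes: Sequence[int] = (30,),
    regimes: Sequence[Regime] = ("dynamic",),
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Accuracy-by-time sweep over (noise, readout time, hidden size, seed).

    Returns one row per cell: noise, regime, depth, hidden_size, seed,
    accuracy, n_trials.  A cell whose training diverges is recorded with NaN
    accuracy and the sweep continues.
    """
    rows = []
    for regime in regimes:
        for noise in noise_levels:
            for hidden in hidden_sizes:
                for depth in readout_times:
                    for seed in seeds:
                        cfg = replace(base, readout_time=int(depth), noise_level=noise,
                                      hidden_size=hidden, regime=regime, seed=seed)
                        try:
                            res = train_supervised(cfg)
                            acc, n = res.accuracy, res.n_eval
                        except FloatingPointError:
                            acc, n = np.nan, 0
                        rows.append(dict(noise=noise, regime=regime, depth=int(depth),
                                         hidden_size=hidden, seed=seed,
                                         accuracy=acc, n_trials=n))
    return pd.DataFrame(rows)
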