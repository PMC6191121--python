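"""Behavioral and neural analyses of trained networks.

Covers: exponential fits to accuracy-over-time curves, the time-to-90%-of-
maximum statistic, psychometric (accuracy vs signal strength) and
chronometric (observations vs signal strength) summaries with fits,
trial-length distributions and the correct-vs-incorrect comparison,
generalization and speed-accuracy experiments, condition-averaged unit time
courses, k-means clustering of hidden units with elbow selection, and the
psychophysical kernel (time-resolved classification image).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .actor_critic import RLConfig, TrainedAgent, evaluate_agent, train_agent
from .rl_environment import EnvConfig, EpisodeRecord
from .stimuli import DEFAULT_NOISE_LEVELS


# ---------------------------------------------------------------------------
# Accuracy-over-time fits

@dataclass
class ExpFit:
    """Parameters of ``f(t) = A exp(B t) + C``; ``B`` is the growth rate."""

    A: float
    B: float
    C: float
    residual: float          # sum of squared residuals
    converged: bool

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.A * np.exp(self.B * np.asarray(t, dtype=float)) + self.C


def fit_exponential(t: np.ndarray, y: np.ndarray) -> ExpFit:
    """Nonlinear least squares fit of ``A exp(B t) + C``.

    Multi-start over the sign of B; non-convergence is reported in the
    result, never raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")

    def f(t, A, B, C):
        return A * np.exp(np.clip(B * t, -500, 500)) + C

    best: ExpFit | None = None
    for B0 in (-0.5, 0.5, -0.05, 0.05):
        try:
            popt, _ = optimize.curve_fit(
                f, t, y, p0=[y[0] - y[-1], B0, y[-1]], maxfev=20_000)
        except RuntimeError:
            continue
        res = float(np.sum((f(t, *popt) - y) ** 2))
        if best is None or res < best.residual:
            best = ExpFit(*map(float, popt), residual=res, converged=True)
    if best is None:
        return ExpFit(np.nan, np.nan, np.nan, residual=np.inf, converged=False)
    return best


def time_to_fraction_max(accuracy: Sequence[float], fraction: float = 0.9,
                         times: Sequence[int] | None = None) -> int:
    """Smallest time step whose accuracy reaches ``fraction`` of the maximum."""
    acc = np.asarray(accuracy, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy sequence")
    if times is None:
        times = np.arange(1, acc.size + 1)
    threshold = fraction * np.nanmax(acc)
    idx = int(np.argmax(acc >= threshold))
    return int(np.asarray(times)[idx])


# ---------------------------------------------------------------------------
# Behavioral summaries of RL episode logs

def _binom_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = stats.binomtest(k, n).proportion_ci(confidence_level=1 - alpha)
    return float(lo), float(hi)


def behavior_summary(
    records: Sequence[EpisodeRecord],
    bin_width: int | None = None,
) -> pd.DataFrame:
    """Per-noise-level behavioral summary of answered trials.

    Columns: noise, signal_strength, n_total, n_answered, accuracy with
    binomial CI, mean/sem of trial length, mean length on correct and
    incorrect trials with a two-sample rank-test p-value (NaN when either
    side is empty), and the trial-length histogram (optionally re-binned by
    ``bin_width`` steps and normalized per noise level).
    """
    if not records:
        raise ValueError("no episodes")
    rows = []
    for noise in sorted({r.noise_proportion for r in records}):
        cell = [r for r in records if r.noise_proportion == noise]
        answered = [r for r in cell if r.answered]
        lengths = np.array([r.n_steps for r in answered])
        correct_len = np.array([r.n_steps for r in answered if r.correct])
        incorrect_len = np.array([r.n_steps for r in answered if not r.correct])
        if len(answered):
            k = int(sum(r.correct for r in answered))
            acc = k / len(answered)
            ci = _binom_ci(k, len(answered))
        else:
            acc, ci = np.nan, (np.nan, np.nan)
        if len(correct_len) and len(incorrect_len):
            stat, p = stats.mannwhitneyu(correct_len, incorrect_len,
                                         alternative="two-sided")
        else:
            stat, p = np.nan, np.nan
        max_len = max((r.n_steps for r in cell), default=0)
        hist = np.bincount(lengths, minlength=max_len + 1) if len(lengths) else np.zeros(1)
        if bin_width:
            pad = (-len(hist)) % bin_width
            hist = np.pad(hist, (0, pad)).reshape(-1, bin_width).sum(axis=1)
            hist = hist / max(len(cell), 1)
        rows.append(dict(
            noise=noise, signal_strength=100 * (1 - noise),
            n_total=len(cell), n_answered=len(answered),
            accuracy=acc, acc_ci_low=ci[0], acc_ci_high=ci[1],
            mean_obs=lengths.mean() if len(lengths) else np.nan,
            sem_obs=stats.sem(lengths) if len(lengths) > 1 else np.nan,
            mean_len_correct=correct_len.mean() if len(correct_len) else np.nan,
            mean_len_incorrect=incorrect_len.mean() if len(incorrect_len) else np.nan,
            ranksum_p=p, length_hist=hist,
        ))
    return pd.DataFrame(rows)


def fit_psychometric(signal_strength: np.ndarray, accuracy: np.ndarray):
    """Cumulative-Weibull fit of accuracy vs signal strength (2AFC floor 0.5).

    Returns ``(params, fitted_fn)``; params are (threshold alpha, slope beta,
    lapse lambda).
    """
    s = np.asarray(signal_strength, dtype=float)
    a = np.asarray(accuracy, dtype=float)

    def weib(s, alpha, beta, lapse):
        return 0.5 + (0.5 - lapse) * (1 - np.exp(-((np.maximum(s, 1e-9) / alpha) ** beta)))

    p0 = [max(np.median(s), 1.0), 2.0, 0.02]
    try:
        popt, _ = optimize.curve_fit(
            weib, s, a, p0=p0, bounds=([1e-6, 0.1, 0.0], [1e4, 20.0, 0.5]),
            maxfev=20_000)
    except RuntimeError:
        popt = np.array(p0)
    return tuple(map(float, popt)), (lambda x: weib(np.asarray(x, float), *popt))


def fit_chronometric(signal_strength: np.ndarray, mean_obs: np.ndarray):
    """Ordinary least-squares line through mean observations vs signal strength."""
    res = stats.linregress(signal_strength, mean_obs)
    return (float(res.slope), float(res.intercept)), res


# ---------------------------------------------------------------------------
# Experiments: generalization and speed-accuracy trade-off

def run_generalization(
    env_config: EnvConfig,
    rl_config: RLConfig,
    train_levels: Sequence[float] = (0.0, 0.75),
    test_levels: Sequence[float] = DEFAULT_NOISE_LEVELS,
    n_eval: int = 200,
) -> tuple[TrainedAgent, pd.DataFrame]:
    """Train on a subset of noise levels, evaluate the frozen policy on all.

    Emulates the interpolation/extrapolation experiment: an agent exposed
    only to two levels is probed at unseen intermediate and more extreme
    levels.
    """
    cfg_train = replace(env_config, noise_levels=tuple(train_levels))
    agent, _ = train_agent(cfg_train, rl_config)
    cfg_test = replace(env_config, noise_levels=tuple(test_levels))
    records = evaluate_agent(agent, cfg_test, n_eval, seed=rl_config.seed,
                             proportions=test_levels)
    summary = behavior_summary(records)
    summary["trained_on"] = [p in set(train_levels) for p in summary["noise"]]
    return agent, summary


def run_speed_accuracy(
    env_config: EnvConfig,
    rl_config: RLConfig,
    costs: Sequence[float] = (0.0, -0.005, -0.01),
    n_eval: int = 200,
) -> pd.DataFrame:
    """Train one agent per observation cost and summarize behavior per cost."""
    frames = []
    for cost in costs:
        cfg = replace(env_config, observation_cost=cost)
        agent, _ = train_agent(cfg, rl_config)
        records = evaluate_agent(agent, cfg, n_eval, seed=rl_config.seed,
                                 proportions=env_config.noise_levels)
        s = behavior_summary(records)
        s["observation_cost"] = cost
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Neural analyses

def unit_time_courses(
    records: Sequence[EpisodeRecord],
    horizon: int | None = None,
    which: str = "hidden_policy",
) -> dict[tuple[float, int], np.ndarray]:
    """Condition-averaged activity per unit, aligned to trial start.

    Conditions are (noise level, stimulus label).  Returns a dict mapping
    each condition to an array ``(horizon, n_units)``; trials shorter than a
    probe step are excluded from that step's average.  ``which`` may also be
    ``"pis"`` for the output (policy probability) traces.
    """
    if not records:
        raise ValueError("no episodes")
    for r in records:
        if getattr(r, which) is None or len(getattr(r, which)) == 0:
            raise ValueError("episodes lack the requested activity traces")
    if horizon is None:
        horizon = max(r.n_steps for r in records)
    out: dict[tuple[float, int], np.ndarray] = {}
    conditions = sorted({(r.noise_proportion, r.label) for r in records})
    for cond in conditions:
        trials = [getattr(r, which) for r in records
                  if (r.noise_proportion, r.label) == cond]
        n_units = trials[0].shape[1]
        acc = np.zeros((horizon, n_units))
        cnt = np.zeros(horizon)
        for tr in trials:
            T = min(len(tr), horizon)
            acc[:T] += tr[:T]
            cnt[:T] += 1
        with np.errstate(invalid="ignore"):
            out[cond] = acc / cnt[:, None]
    return out


def unit_feature_matrix(
    courses: dict[tuple[float, int], np.ndarray], zscore: bool = True
) -> np.ndarray:
    """Stack each unit's condition-averaged traces into one feature row.

    Rows = hidden units, columns = concatenated (condition x time) means;
    NaN steps (no trial that long) are replaced by the last valid value.
    Per-unit z-scoring makes clustering shape-sensitive rather than
    amplitude-sensitive.
    """
    mats = []
    for cond in sorted(courses):
        m = courses[cond].copy()          # (horizon, n_units)
        for j in range(m.shape[1]):
            col = m[:, j]
            if np.any(np.isnan(col)):
                valid = np.flatnonzero(~np.isnan(col))
                col[np.isnan(col)] = col[valid[-1]] if len(valid) else 0.0
        mats.append(m.T)
    X = np.concatenate(mats, axis=1)      # (n_units, total_len)
    if zscore:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    return X


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    d: float                 # within-cluster sum of squared distances


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """Lloyd's k-means (best of 10 restarts) minimizing the within-cluster
    sum of squared distances ``d = sum_k sum_{x in C_k} ||x - mu_k||^2``."""
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of points {len(X)}")
    km = KMeans(n_clusters=k, n_init=10, algorithm="lloyd",
                random_state=seed).fit(X)
    return ClusterResult(k=k, assignments=km.labels_.copy(),
                         centroids=km.cluster_centers_.copy(),
                         d=float(km.inertia_))


def elbow_select(ks: Sequence[int], ds: Sequence[float]) -> tuple[int, bool]:
    """Elbow of the d-vs-k curve: the k maximizing perpendicular distance to
    the chord from the first to the last point.

    Returns ``(k_star, has_elbow)``; a (numerically) straight curve has no
    elbow and the first k is returned flagged.
    """
    ks = np.asarray(ks, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate k values")
    # normalize both axes so the geometry is scale-free
    kk = (ks - ks[0]) / max(ks[-1] - ks[0], 1e-12)
    span = max(abs(ds[0] - ds[-1]), 1e-12)
    dd = (ds - ds[-1]) / span
    chord = np.array([kk[-1] - kk[0], dd[-1] - dd[0]])
    chord /= np.linalg.norm(chord)
    rel = np.stack([kk - kk[0], dd - dd[0]], axis=1)
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    if dist.max() < 1e-9:
        return int(ks[0]), False
    return int(ks[int(np.argmax(dist))]), True


def cluster_hidden_units(
    records: Sequence[EpisodeRecord],
    k_max: int = 8,
    horizon: int | None = None,
    seed: int = 0,
    which: str = "hidden_policy",
) -> tuple[ClusterResult, pd.DataFrame]:
    """End-to-end hidden-unit clustering: condition-averaged traces ->
    feature matrix -> k-means over k=1..k_max -> elbow selection."""
    courses = unit_time_courses(records, horizon=horizon, which=which)
    X = unit_feature_matrix(courses)
    ks = list(range(1, min(k_max, len(X)) + 1))
    results = {k: kmeans_cluster(X, k, seed=seed) for k in ks}
    ds = [results[k].d for k in ks]
    k_star, _ = elbow_select(ks, ds)
    curve = pd.DataFrame(dict(k=ks, d=ds))
    return results[k_star], curve


# ---------------------------------------------------------------------------
# Psychophysical kernel (time-resolved classification image)

def psychophysical_kernel(
    records: Sequence[EpisodeRecord],
    pre_stimulus_steps: int = 3,
    min_count: int = 1,
) -> pd.DataFrame:
    """``PK_t = <s_t | D=1> - <s_t | D=2>`` per post-onset time step.

    The classification image at step t is the difference between the mean
    stimulus frame in view at t over trials decided for class 1 and over
    trials decided for class 2; the reported amplitude is the mean absolute
    pixel value of that difference image.  Steps with fewer than
    ``min_count`` trials of either decision are omitted.
    """
    d1 = [r for r in records if r.decision == 1]
    d2 = [r for r in records if r.decision == 2]
    if not d1 or not d2:
        raise ValueError("need trials ending in both decisions")
    # only post-onset frames carry a kernel; earlier observations are all zero
    pre = pre_stimulus_steps
    horizon = max(r.n_steps for r in records)
    rows = []
    for t in range(pre, horizon):
        f1 = [r.observations[t] for r in d1 if r.n_steps > t]
        f2 = [r.observations[t] for r in d2 if r.n_steps > t]
        if len(f1) < min_count or len(f2) < min_count:
            continue
        diff = np.mean(f1, axis=0) - np.mean(f2, axis=0)
        rows.append(dict(t=t, n_d1=len(f1), n_d2=len(f2),
                         amplitude=float(np.mean(np.abs(diff))),
                         image=diff))
    if not rows:
        raise ValueError("no step has enough trials of both decisions")
    return pd.DataFrame(rows)
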