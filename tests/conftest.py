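import numpy as np
import pytest

from evint.grunet import init_gru, init_readout
from evint.actor_critic import RLConfig, TrainedAgent
from evint.rl_environment import EnvConfig, EpisodeRecord, Outcome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def finite_difference(f, arrays, h=1e-4):
    """Central finite differences of scalar ``f()`` w.r.t. every entry of the
    given named arrays; returns {name: grad array}."""
    out = {}
    for name, arr in arrays.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = arr[i]
            arr[i] = old + h
            fp = f()
            arr[i] = old - h
            fm = f()
            arr[i] = old
            g[i] = (fp - fm) / (2 * h)
        out[name] = g
    return out


def max_rel_err(analytic: dict, numeric: dict) -> float:
    worst = 0.0
    for name in analytic:
        a, n = analytic[name], numeric[name]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-8)
        worst = max(worst, float(np.max(np.abs(a - n) / denom)))
    return worst


def make_tiny_agent(n_in=4, n_hidden=5, seed=2, **rl_kwargs) -> TrainedAgent:
    r = np.random.default_rng(seed)
    return TrainedAgent(
        policy_gru=init_gru(n_in, n_hidden, r),
        policy_out=init_readout(n_hidden, 3, r),
        value_gru=init_gru(n_in, n_hidden, r),
        value_out=init_readout(n_hidden, 1, r),
        rl_config=RLConfig(hidden_size=n_hidden, **rl_kwargs),
        env_config=EnvConfig(grid=(8, 8)),
    )


def make_toy_episode(rng, T, n_in=4, n_hidden=5) -> EpisodeRecord:
    return EpisodeRecord(
        observations=rng.uniform(0, 1, size=(T, n_in)),
        actions=rng.integers(0, 3, size=T),
        pis=np.full((T, 3), 1 / 3),
        rewards=rng.normal(0, 1, size=T),
        values=np.zeros(T),
        hidden_policy=np.zeros((T, n_hidden)),
        hidden_value=np.zeros((T, n_hidden)),
        label=0,
        noise_proportion=0.5,
        outcome=Outcome.CORRECT,
    )
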