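"""Gated recurrent network core with hand-written backpropagation through time.

The recurrent layer is a GRU variant with a temporal constant ``tau`` and a
sigmoid (not tanh) hidden nonlinearity, so hidden activities stay in (0, 1)
and are interpretable as normalized firing rates:

    r_t = sigmoid(U_r x_t + W_r h_{t-1} + b_r)
    z_t = sigmoid(U_z x_t + W_z h_{t-1} + b_z)
    h_t = tau * z_t (.) h_{t-1} + (1 - tau * z_t) (.) sigmoid(U_c x_t + W_h (r_t (.) h_{t-1}) + b_h)

where (.) is the Hadamard product.  ``r`` and ``z`` are the reset and update
gates; ``tau`` in (0, 1] shortens the effective memory (with tau < 1 the cell
can never freeze its state completely, since tau*z < 1).  A dense readout
maps hidden activity to output; the softmax, when needed, is applied by the
consumer.

Two candidate-term wirings are supported: the standard form with its own
input matrix ``U_c`` (default), and ``tied_candidate_input=True`` which
reuses ``U_z`` inside the candidate.

All forward passes operate on batches ``(B, n)`` in float64.  Gradients are
computed by an explicit reverse pass (:func:`gru_step_backward`,
:func:`unroll_backward`); their correctness against central finite
differences is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import NamedTuple

import json
import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUParams:
    """All learned parameters of one recurrent layer."""

    U_r: np.ndarray
    W_r: np.ndarray
    b_r: np.ndarray
    U_z: np.ndarray
    W_z: np.ndarray
    b_z: np.ndarray
    U_c: np.ndarray
    W_h: np.ndarray
    b_h: np.ndarray
    tau: float = 0.5
    tied_candidate_input: bool = False

    def __post_init__(self) -> None:
        n_in, n_h = self.U_r.shape
        for name, mat in (("U_z", self.U_z), ("U_c", self.U_c)):
            if mat.shape != (n_in, n_h):
                raise ValueError(f"{name} shape {mat.shape} != {(n_in, n_h)}")
        for name, mat in (("W_r", self.W_r), ("W_z", self.W_z), ("W_h", self.W_h)):
            if mat.shape != (n_h, n_h):
                raise ValueError(f"{name} shape {mat.shape} != {(n_h, n_h)}")
        for name, vec in (("b_r", self.b_r), ("b_z", self.b_z), ("b_h", self.b_h)):
            if vec.shape != (n_h,):
                raise ValueError(f"{name} shape {vec.shape} != {(n_h,)}")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau must lie in (0,1], got {self.tau}")

    @property
    def n_inputs(self) -> int:
        return self.U_r.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.U_r.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if isinstance(getattr(self, f.name), np.ndarray)}


@dataclass
class ReadoutParams:
    """Dense layer: hidden activations -> output (affine, no nonlinearity)."""

    W_out: np.ndarray
    b_out: np.ndarray

    def __post_init__(self) -> None:
        if self.b_out.shape != (self.W_out.shape[1],):
            raise ValueError("readout bias/weight shapes inconsistent")

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W_out": self.W_out, "b_out": self.b_out}


def init_gru(
    n_inputs: int,
    n_hidden: int,
    rng: np.random.Generator,
    tau: float = 0.5,
    tied_candidate_input: bool = False,
) -> GRUParams:
    """Fan-in-scaled uniform initialization, deterministic under ``rng``."""

    def u(n_in, n_out):
        s = 1.0 / np.sqrt(n_in)
        return rng.uniform(-s, s, size=(n_in, n_out))

    return GRUParams(
        U_r=u(n_inputs, n_hidden), W_r=u(n_hidden, n_hidden), b_r=np.zeros(n_hidden),
        U_z=u(n_inputs, n_hidden), W_z=u(n_hidden, n_hidden), b_z=np.zeros(n_hidden),
        U_c=u(n_inputs, n_hidden), W_h=u(n_hidden, n_hidden), b_h=np.zeros(n_hidden),
        tau=tau, tied_candidate_input=tied_candidate_input,
    )


def init_readout(n_hidden: int, n_outputs: int, rng: np.random.Generator) -> ReadoutParams:
    s = 1.0 / np.sqrt(n_hidden)
    return ReadoutParams(W_out=rng.uniform(-s, s, size=(n_hidden, n_outputs)),
                         b_out=np.zeros(n_outputs))


class StepCache(NamedTuple):
    """Intermediates of one forward step, consumed by the reverse pass."""

    x: np.ndarray
    h_prev: np.ndarray
    r: np.ndarray
    z: np.ndarray
    c: np.ndarray


def gru_step(params: GRUParams, h_prev: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, StepCache]:
    """One recurrence step; ``x`` is ``(B, n_in)``, ``h_prev`` is ``(B, n_h)``."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    if x.shape[1] != params.n_inputs or h_prev.shape[1] != params.n_hidden:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, h {h_prev.shape}, "
            f"expected inputs {params.n_inputs}, hidden {params.n_hidden}")
    r = sigmoid(x @ params.U_r + h_prev @ params.W_r + params.b_r)
    z = sigmoid(x @ params.U_z + h_prev @ params.W_z + params.b_z)
    U_c = params.U_z if params.tied_candidate_input else params.U_c
    c = sigmoid(x @ U_c + (r * h_prev) @ params.W_h + params.b_h)
    h = params.tau * z * h_prev + (1.0 - params.tau * z) * c
    return h, StepCache(x=x, h_prev=h_prev, r=r, z=z, c=c)


def gru_step_backward(
    params: GRUParams, cache: StepCache, dh: np.ndarray, grads: dict[str, np.ndarray]
) -> np.ndarray:
    """Reverse one step: given dL/dh_t, accumulate parameter gradients into
    ``grads`` (summed over the batch) and return dL/dh_{t-1}."""
    x, h_prev, r, z, c = cache
    tau = params.tau
    # h = tau*z*h_prev + (1 - tau*z)*c
    dz = dh * tau * (h_prev - c)
    dc = dh * (1.0 - tau * z)
    dh_prev = dh * tau * z
    # candidate pre-activation
    dc_pre = dc * c * (1.0 - c)
    da = dc_pre @ params.W_h.T          # a = r * h_prev
    dr = da * h_prev
    dh_prev = dh_prev + da * r
    dr_pre = dr * r * (1.0 - r)
    dz_pre = dz * z * (1.0 - z)
    dh_prev = dh_prev + dr_pre @ params.W_r.T + dz_pre @ params.W_z.T

    grads["W_h"] += (r * h_prev).T @ dc_pre
    grads["b_h"] += dc_pre.sum(axis=0)
    grads["W_r"] += h_prev.T @ dr_pre
    grads["b_r"] += dr_pre.sum(axis=0)
    grads["W_z"] += h_prev.T @ dz_pre
    grads["b_z"] += dz_pre.sum(axis=0)
    grads["U_r"] += x.T @ dr_pre
    if params.tied_candidate_input:
        grads["U_z"] += x.T @ (dz_pre + dc_pre)
    else:
        grads["U_z"] += x.T @ dz_pre
        grads["U_c"] += x.T @ dc_pre
    return dh_prev


def readout(params: ReadoutParams, h: np.ndarray) -> np.ndarray:
    """Affine readout; softmax (if any) is the consumer's business."""
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if h.shape[1] != params.W_out.shape[0]:
        raise ValueError(f"hidden size {h.shape[1]} != readout rows {params.W_out.shape[0]}")
    return h @ params.W_out + params.b_out


def readout_backward(
    params: ReadoutParams, h: np.ndarray, dz: np.ndarray, grads: dict[str, np.ndarray]
) -> np.ndarray:
    grads["W_out"] += h.T @ dz
    grads["b_out"] += dz.sum(axis=0)
    return dz @ params.W_out.T


def zero_grads(*param_sets) -> dict[str, np.ndarray]:
    g: dict[str, np.ndarray] = {}
    for p in param_sets:
        for name, arr in p.arrays().items():
            g[name] = np.zeros_like(arr)
    return g


def unroll(
    params: GRUParams,
    readout_params: ReadoutParams,
    inputs: np.ndarray,
    h0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[StepCache]]:
    """Run the network over ``inputs`` of shape ``(T, B, n_in)`` (or
    ``(T, n_in)`` for a single trial).

    Returns hidden trajectories ``(T, B, n_h)``, outputs ``(T, B, n_out)``
    and the per-step caches for the reverse pass.  The initial state
    defaults to all-zeros, reset at every trial.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    squeeze = inputs.ndim == 2
    if squeeze:
        inputs = inputs[:, None, :]
    if inputs.shape[0] == 0:
        raise ValueError("empty frame sequence")
    T, B, _ = inputs.shape
    h = np.zeros((B, params.n_hidden)) if h0 is None else np.atleast_2d(h0)
    hs = np.empty((T, B, params.n_hidden))
    outs = np.empty((T, B, readout_params.b_out.shape[0]))
    caches: list[StepCache] = []
    for t in range(T):
        h, cache = gru_step(params, h, inputs[t])
        hs[t] = h
        outs[t] = readout(readout_params, h)
        caches.append(cache)
    if squeeze:
        return hs[:, 0], outs[:, 0], caches
    return hs, outs, caches


def unroll_backward(
    params: GRUParams,
    readout_params: ReadoutParams,
    hs: np.ndarray,
    caches: list[StepCache],
    d_outs: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    """Backpropagate through time.

    ``d_outs`` holds dL/d(output_t) for every step, shape matching the
    outputs of :func:`unroll` (zero rows for steps that do not enter the
    loss).  Parameter gradients are accumulated into ``grads``.
    """
    d_outs = np.asarray(d_outs, dtype=np.float64)
    if d_outs.ndim == 2:
        d_outs = d_outs[:, None, :]
        hs = hs[:, None, :]
    T = len(caches)
    dh = np.zeros_like(hs[0])
    for t in range(T - 1, -1, -1):
        dz = d_outs[t]
        if np.any(dz):
            dh = dh + readout_backward(readout_params, hs[t], dz, grads)
        dh = gru_step_backward(params, caches[t], dh, grads)


# ---------------------------------------------------------------------------
# Checkpoint I/O: array container + JSON sidecar with shapes/flags.

def save_checkpoint(path: str | Path, gru: GRUParams, out: ReadoutParams) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **gru.arrays(), **out.arrays())
    meta = {
        "tau": gru.tau,
        "tied_candidate_input": gru.tied_candidate_input,
        "n_inputs": gru.n_inputs,
        "n_hidden": gru.n_hidden,
        "n_outputs": int(out.b_out.shape[0]),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[GRUParams, ReadoutParams]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        arrs = {k: data[k] for k in data.files}
    gru = GRUParams(
        **{k: arrs[k] for k in ("U_r", "W_r", "b_r", "U_z", "W_z", "b_z", "U_c", "W_h", "b_h")},
        tau=meta["tau"], tied_candidate_input=meta["tied_candidate_input"],
    )
    out = ReadoutParams(W_out=arrs["W_out"], b_out=arrs["b_out"])
    return gru, out
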