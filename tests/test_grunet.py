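import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evint.grunet import (
    GRUParams, ReadoutParams, gru_step, init_gru, init_readout, load_checkpoint,
    readout, save_checkpoint, sigmoid, unroll, unroll_backward, zero_grads,
)
from conftest import finite_difference, max_rel_err


def zero_params(n_in, n_h, tau=0.5, tied=False):
    z = lambda *s: np.zeros(s)
    return GRUParams(U_r=z(n_in, n_h), W_r=z(n_h, n_h), b_r=z(n_h),
                     U_z=z(n_in, n_h), W_z=z(n_h, n_h), b_z=z(n_h),
                     U_c=z(n_in, n_h), W_h=z(n_h, n_h), b_h=z(n_h),
                     tau=tau, tied_candidate_input=tied)


class TestGruStep:
    def test_zero_weights_zero_state_closed_form(self):
        # r = z = c = sigmoid(0) = 0.5; h = 0.5*0.5*0 + (1-0.25)*0.5 = 0.375
        p = zero_params(3, 4)
        h, _ = gru_step(p, np.zeros((1, 4)), np.ones((1, 3)))
        assert np.allclose(h, 0.375)

    def test_zero_weights_ones_state_closed_form(self):
        # h = 0.25*1 + 0.75*0.5 = 0.625
        p = zero_params(3, 4)
        h, _ = gru_step(p, np.ones((1, 4)), np.ones((1, 3)))
        assert np.allclose(h, 0.625)

    def test_matches_independent_transcription(self, rng):
        p = init_gru(6, 5, rng)
        x = rng.uniform(0, 1, (2, 6))
        h_prev = rng.uniform(0, 1, (2, 5))
        h, _ = gru_step(p, h_prev, x)
        # independent line-by-line transcription of the update equations
        sig = lambda a: 1 / (1 + np.exp(-a))
        r = sig(x @ p.U_r + h_prev @ p.W_r + p.b_r)
        z = sig(x @ p.U_z + h_prev @ p.W_z + p.b_z)
        c = sig(x @ p.U_c + p.b_h + (r * h_prev) @ p.W_h)
        expect = p.tau * z * h_prev + (1 - p.tau * z) * c
        assert np.allclose(h, expect, atol=1e-12)

    def test_tied_candidate_uses_update_gate_input_matrix(self, rng):
        p = init_gru(6, 5, rng, tied_candidate_input=True)
        x = rng.uniform(0, 1, (1, 6))
        h_prev = rng.uniform(0, 1, (1, 5))
        h, _ = gru_step(p, h_prev, x)
        sig = lambda a: 1 / (1 + np.exp(-a))
        r = sig(x @ p.U_r + h_prev @ p.W_r + p.b_r)
        z = sig(x @ p.U_z + h_prev @ p.W_z + p.b_z)
        c = sig(x @ p.U_z + p.b_h + (r * h_prev) @ p.W_h)   # U_z reused
        assert np.allclose(h, p.tau * z * h_prev + (1 - p.tau * z) * c, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        p = init_gru(3, 4, rng)
        with pytest.raises(ValueError):
            gru_step(p, np.zeros((1, 4)), np.zeros((1, 5)))
        with pytest.raises(ValueError):
            GRUParams(**{**zero_params(3, 4).arrays()}, tau=1.5)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**16), scale=st.floats(0.1, 20))
    def test_hidden_activity_stays_in_unit_interval(self, seed, scale):
        # tau*z < 1 always, so h is a convex mix of values in (0,1); at
        # extreme pre-activations the sigmoid rounds to 1.0 in float64, so
        # the strict upper bound is checked up to machine precision
        r = np.random.default_rng(seed)
        p = init_gru(3, 4, r)
        for arr in p.arrays().values():
            arr *= scale
        h = r.uniform(0, 1, (1, 4))
        for x in r.uniform(-5, 5, (5, 1, 3)):
            h, _ = gru_step(p, h, x)
            assert np.all(h > 0) and np.all(h <= 1.0)

    def test_gate_saturation_limits(self):
        # z -> 1 with tau = 1: perfect memory; z -> 0: pure candidate
        p = zero_params(3, 4, tau=1.0)
        h_prev = np.full((1, 4), 0.73)
        x = np.zeros((1, 3))
        p.b_z[:] = 50.0
        h, _ = gru_step(p, h_prev, x)
        assert np.allclose(h, h_prev, atol=1e-12)
        p.b_z[:] = -50.0
        p.b_h[:] = 2.0
        h, _ = gru_step(p, h_prev, x)
        assert np.allclose(h, sigmoid(np.full(4, 2.0)), atol=1e-12)


class TestReadout:
    def test_constant_and_identity_maps(self, rng):
        p = ReadoutParams(W_out=np.zeros((4, 3)), b_out=np.array([1.0, 2.0, 3.0]))
        assert np.allclose(readout(p, rng.uniform(size=(2, 4))), [1, 2, 3])
        p = ReadoutParams(W_out=np.eye(4), b_out=np.zeros(4))
        h = rng.uniform(size=(1, 4))
        assert np.allclose(readout(p, h), h)

    def test_matches_matrix_vector_oracle(self, rng):
        p = init_readout(5, 3, rng)
        h = rng.uniform(size=(2, 5))
        expect = np.array([[h[i] @ p.W_out[:, j] + p.b_out[j] for j in range(3)]
                           for i in range(2)])
        assert np.allclose(readout(p, h), expect, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            readout(init_readout(5, 3, rng), np.zeros((1, 4)))


class TestUnroll:
    def test_single_frame_equals_single_step(self, rng):
        p = init_gru(3, 4, rng)
        out = init_readout(4, 2, rng)
        x = rng.uniform(size=(1, 3))
        hs, outs, _ = unroll(p, out, x)
        h1, _ = gru_step(p, np.zeros((1, 4)), x[0])
        assert np.allclose(hs[0], h1[0])
        assert np.allclose(outs[0], readout(out, h1)[0])

    def test_zero_weight_scalar_recursion(self):
        # with all weights zero: h_t = 0.25 h_{t-1} + 0.375 elementwise
        p = zero_params(3, 4)
        out = ReadoutParams(W_out=np.zeros((4, 1)), b_out=np.zeros(1))
        hs, _, _ = unroll(p, out, np.ones((6, 3)))
        h = 0.0
        for t in range(6):
            h = 0.25 * h + 0.375
            assert np.allclose(hs[t], h, atol=1e-12)

    def test_noise_regimes_coincide_at_zero_proportion(self, rng):
        from evint.stimuli import NoiseSpec, make_class_templates, make_trial
        tpl = make_class_templates(2, (8, 8), variability=0.0, seed=0)
        p = init_gru(64, 4, rng)
        out = init_readout(4, 2, rng)
        trajs = []
        for regime in ("static", "dynamic"):
            trial = make_trial(0, NoiseSpec(proportion=0.0, regime=regime, seed=9),
                               tpl, 5)
            hs, _, _ = unroll(p, out, trial.flat())
            trajs.append(hs)
        assert np.array_equal(trajs[0], trajs[1])

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            unroll(init_gru(3, 4, rng), init_readout(4, 2, rng), np.zeros((0, 3)))


class TestBPTTGradients:
    @pytest.mark.parametrize("tied", [False, True])
    def test_match_central_finite_differences(self, rng, tied):
        gru = init_gru(3, 4, rng, tied_candidate_input=tied)
        out = init_readout(4, 2, rng)
        X = rng.uniform(0, 1, size=(3, 2, 3))
        W = rng.normal(size=(3, 2, 2))     # weights making a scalar of all outputs

        def scalar():
            _, outs, _ = unroll(gru, out, X)
            return float(np.sum(W * outs))

        hs, outs, caches = unroll(gru, out, X)
        grads = zero_grads(gru, out)
        unroll_backward(gru, out, hs, caches, W.copy(), grads)
        arrays = {**gru.arrays(), **out.arrays()}
        if tied:
            arrays.pop("U_c")          # inert when the candidate input is tied
            grads.pop("U_c")
        num = finite_difference(scalar, arrays)
        assert max_rel_err(grads, num) < 1e-5

    def test_loss_restricted_to_final_step_skips_earlier_readouts(self, rng):
        gru = init_gru(3, 4, rng)
        out = init_readout(4, 2, rng)
        X = rng.uniform(size=(4, 1, 3))
        hs, outs, caches = unroll(gru, out, X)
        d_outs = np.zeros_like(outs)
        d_outs[-1] = 1.0
        grads = zero_grads(gru, out)
        unroll_backward(gru, out, hs, caches, d_outs, grads)
        # readout gradient must involve only the final hidden state
        assert np.allclose(grads["W_out"], hs[-1].T @ d_outs[-1])


def test_checkpoint_roundtrip(tmp_path, rng):
    gru = init_gru(3, 4, rng, tau=0.7, tied_candidate_input=True)
    out = init_readout(4, 2, rng)
    save_checkpoint(tmp_path / "ck", gru, out)
    gru2, out2 = load_checkpoint(tmp_path / "ck")
    assert gru2.tau == 0.7 and gru2.tied_candidate_input
    for k, v in gru.arrays().items():
        assert np.array_equal(v, gru2.arrays()[k])
    assert np.array_equal(out.W_out, out2.W_out)
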