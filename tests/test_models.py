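"""LSTM chain, residual stack, losses and parameter accounting."""

import numpy as np
import pytest

from bolusrec import (
    LSTMChain, LSTMChainConfig, ResidualStack, ResidualStackConfig,
    count_parameters, training_loss,
)
from bolusrec.autodiff import Adam, Tensor, lstm_seq, parameter
from bolusrec.recommender_models import (
    EncodedExample, lstm_chain_forward, residual_stack_forward,
)

TINY = LSTMChainConfig(state_size=4, fc_layers=1, fc_width=8,
                       extra_features=3)


def random_batch(rng, B=3, hist_len=12, win_len=9, extras=3):
    return (rng.normal(size=(B, hist_len, 4)), rng.normal(size=(B, win_len, 3)),
            rng.normal(size=(B, extras)), rng.normal(size=B))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestLSTMSeq:
    def test_matches_stepwise_reference(self, rng):
        """Fused sequence op agrees with a plain per-step NumPy LSTM."""
        B, T, C, H = 2, 6, 3, 4
        x = rng.normal(size=(B, T, C))
        W = parameter(rng.normal(size=(C + H, 4 * H)) * 0.3)
        b = parameter(rng.normal(size=4 * H) * 0.1)
        out = lstm_seq(x, W, b)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        sig = lambda v: 1 / (1 + np.exp(-v))
        for t in range(T):
            z = np.concatenate([x[:, t], h], axis=1) @ W.data + b.data
            i, f = sig(z[:, :H]), sig(z[:, H:2 * H])
            g, o = np.tanh(z[:, 2 * H:3 * H]), sig(z[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
        np.testing.assert_allclose(out.data, h, atol=1e-12)


class TestLSTMChain:
    def test_zero_params_output_is_bias(self, rng):
        m = LSTMChain(TINY, seed=0)
        for p in m.params.values():
            p.data[:] = 0.0
        m.params["out.b"].data[:] = 0.7
        hist, win, extras, _ = random_batch(rng)
        out = m.forward(hist, win, extras)
        np.testing.assert_allclose(out.data, 0.7, atol=1e-12)

    def test_inference_deterministic(self, rng):
        m = LSTMChain(LSTMChainConfig(state_size=4, fc_layers=2, fc_width=8,
                                      dropout=0.4), seed=1)
        hist, win, extras, _ = random_batch(rng)
        a = m.forward(hist, win, extras).data
        b = m.forward(hist, win, extras).data
        np.testing.assert_array_equal(a, b)

    def test_inertial_estimate_varies_with_tau(self, rng):
        """With all-zero window channels, tau still reaches the output via the
        unroll length and the horizon feature."""
        m = LSTMChain(TINY, seed=2)
        hist = rng.normal(size=(1, 12, 4))
        extras = rng.normal(size=(1, 3))
        outs = []
        for steps, tau_feat in ((8, 0.0), (14, 0.5), (20, 1.0)):
            ex = extras.copy()
            ex[0, 1] = tau_feat
            win = np.zeros((1, steps, 3))
            outs.append(m.forward(hist, win, ex).data.item())
        assert len(set(np.round(outs, 12))) == 3

    def test_single_example_wrapper(self, rng):
        m = LSTMChain(TINY, seed=3)
        hist, win, extras, _ = random_batch(rng, B=1)
        enc = EncodedExample(history=hist[0], window=win[0], extras=extras[0],
                             label=0.0)
        assert lstm_chain_forward(enc, m) == pytest.approx(
            m.forward(hist, win, extras).data.item())


class TestResidualStack:
    def _stack(self, blocks, seed=5, joint=True):
        return ResidualStack(ResidualStackConfig(
            blocks=blocks, block=TINY, backcast_length=12, joint_head=joint),
            seed=seed)

    def test_blocks_zero_rejected(self):
        with pytest.raises(ValueError):
            ResidualStackConfig(blocks=0, block=TINY)

    def test_one_block_equals_chain_forecast_coordinate(self, rng):
        """A 1-block stack is the plain chain whose output head is the
        forecast column of the joint 73-wide head."""
        stack = self._stack(1)
        L = stack.config.backcast_length
        chain = LSTMChain(TINY, params={
            k.removeprefix("block0."): p for k, p in stack.params.items()})
        chain.params["out.W"] = parameter(
            stack.params["block0.out.W"].data[:, L:L + 1])
        chain.params["out.b"] = parameter(
            stack.params["block0.out.b"].data[L:L + 1])
        hist, win, extras, _ = random_batch(rng)
        est, blocks = stack.forward(hist, win, extras)
        np.testing.assert_allclose(est.data, blocks[0].forecast.data)
        np.testing.assert_allclose(est.data, chain.forward(hist, win, extras).data,
                                   atol=1e-12)

    def test_zeroed_later_blocks_add_only_biases(self, rng):
        stack = self._stack(3)
        L = stack.config.backcast_length
        hist, win, extras, _ = random_batch(rng)
        _, blocks1 = stack.forward(hist, win, extras)
        fore1 = blocks1[0].forecast.data.copy()
        bias_sum = 0.0
        for b in (1, 2):
            for k, p in stack.params.items():
                if k.startswith(f"block{b}."):
                    p.data[:] = 0.0
            stack.params[f"block{b}.out.b"].data[L] = 0.05
            bias_sum += 0.05
        est, _ = stack.forward(hist, win, extras)
        np.testing.assert_allclose(est.data, fore1 + bias_sum, atol=1e-12)

    def test_residual_identity_and_telescoping(self, rng):
        stack = self._stack(4)
        hist, win, extras, _ = random_batch(rng)
        est, blocks = stack.forward(hist, win, extras)
        bg0 = hist[:, :, 0]
        for i in range(1, len(blocks)):
            np.testing.assert_allclose(
                blocks[i].bg_input.data + blocks[i - 1].backcast.data,
                blocks[i - 1].bg_input.data, atol=1e-9)
        final_residual = blocks[-1].bg_input.data - blocks[-1].backcast.data
        total = sum(b.backcast.data for b in blocks) + final_residual
        np.testing.assert_allclose(total, bg0, atol=1e-9)

    def test_separate_heads_supported(self, rng):
        stack = self._stack(2, joint=False)
        hist, win, extras, _ = random_batch(rng)
        est, blocks = stack.forward(hist, win, extras)
        assert blocks[0].backcast.data.shape == (3, 12)
        assert est.data.shape == (3, 1)

    def test_share_weights_halves_parameters(self):
        full = ResidualStackConfig(blocks=4, block=TINY, backcast_length=12)
        shared = ResidualStackConfig(blocks=4, block=TINY, backcast_length=12,
                                     share_weights=True)
        assert count_parameters(shared) * 4 == count_parameters(full)

    def test_single_example_wrapper(self, rng):
        stack = self._stack(2, seed=9)
        hist, win, extras, _ = random_batch(rng, B=1)
        enc = EncodedExample(history=hist[0], window=win[0], extras=extras[0],
                             label=0.0)
        est, blocks = residual_stack_forward(enc, stack)
        assert len(blocks) == 2
        assert est == pytest.approx(stack.forward(hist, win, extras)[0].data.item())


class TestTrainingLoss:
    def test_perfect_fit_is_zero(self):
        from bolusrec.recommender_models import BlockOutput
        est = Tensor([[2.0]])
        blk = BlockOutput(backcast=Tensor([[1.0, 3.0]]), forecast=Tensor([[2.0]]),
                          s1=None, s2=None, bg_input=Tensor([[1.0, 3.0]]))
        assert float(training_loss(est, [blk], np.array([2.0])).data) == 0.0

    def test_alpha_beta_zero_reduces_to_mse(self, rng):
        stack = ResidualStack(ResidualStackConfig(blocks=2, block=TINY,
                                                  backcast_length=12), seed=4)
        hist, win, extras, label = random_batch(rng)
        est, blocks = stack.forward(hist, win, extras)
        plain = float(np.mean((est.data[:, 0] - label) ** 2))
        assert float(training_loss(est, blocks, label, 0.0, 0.0).data) == \
            pytest.approx(plain, rel=1e-12)

    def test_hand_computed_one_block_case(self):
        from bolusrec.recommender_models import BlockOutput
        est = Tensor([[1.0]])
        blk = BlockOutput(backcast=Tensor([[0.2, 0.4]]), forecast=Tensor([[1.0]]),
                          s1=None, s2=None, bg_input=Tensor([[0.1, 0.3]]))
        # (1-0.5)^2 + (1/1)(1-0.5)^2 + (1/1)*mean(0.1^2, 0.1^2) = 0.51
        loss = training_loss(est, [blk], np.array([0.5]))
        assert float(loss.data) == pytest.approx(0.51, abs=1e-12)

    def test_chain_loss_is_plain_mse(self):
        est = Tensor([[2.0], [4.0]])
        loss = training_loss(est, None, np.array([1.0, 5.0]))
        assert float(loss.data) == pytest.approx(1.0)


class TestCountParameters:
    def test_fc_layer_64x64(self):
        small = LSTMChainConfig(state_size=4, fc_layers=1, fc_width=64,
                                extra_features=3)
        grown = LSTMChainConfig(state_size=4, fc_layers=2, fc_width=64,
                                extra_features=3)
        assert count_parameters(grown) - count_parameters(small) == 64 * 64 + 64

    def test_doubling_width_more_than_doubles(self):
        narrow = LSTMChainConfig(state_size=8, fc_layers=2, fc_width=32)
        wide = LSTMChainConfig(state_size=8, fc_layers=2, fc_width=64)
        assert count_parameters(wide) > 2 * count_parameters(narrow)

    def test_matches_enumeration_over_arrays(self):
        m = LSTMChain(TINY, seed=0)
        assert count_parameters(m) == sum(p.data.size for p in m.params.values())
        # closed-form check for the tiny config
        H, W_, E = 4, 8, 3
        expect = ((4 + H) * 4 * H + 4 * H) + (H * 2 * H + 2 * H) + \
                 ((3 + H) * 4 * H + 4 * H) + ((2 * H + E) * W_ + W_) + (W_ + 1)
        assert count_parameters(m) == expect


class TestScaledOutputConsistency:
    def test_affine_identity_scaler_is_transparent(self, rng):
        """With the identity scaler (min 0, max 1 on every channel), encoding
        then predicting equals running the model on the raw arrays."""
        from bolusrec import Scaler
        from bolusrec.train_eval import predict_examples
        from bolusrec.example_builder import RecommendationExample
        sc = Scaler(mins={c: 0.0 for c in ("bg", "carbs", "bolus", "basal", "label")},
                    maxs={c: 1.0 for c in ("bg", "carbs", "bolus", "basal", "label")})
        m = LSTMChain(TINY, seed=6)
        hist = rng.normal(size=(12, 4))
        win = rng.normal(size=(8, 3))
        ex = RecommendationExample(
            subject_id="x", t=0, history=hist, window_events=win,
            target_bg=0.3, tau=30, tod_avg=0.2, label=1.0, inertial=True,
            scenario="carbs_pm_b", wall_minutes=600)
        pred = predict_examples(m, [ex], sc)[0]
        extras = np.array([[0.3, 0.0, 0.2]])
        raw = m.forward(hist[None], win[None], extras).data.item()
        assert pred == pytest.approx(raw, abs=1e-12)


class TestOptimization:
    def test_adam_reduces_loss(self, rng):
        m = LSTMChain(TINY, seed=8)
        hist, win, extras, label = random_batch(rng, B=16)
        opt = Adam(m.params, lr=1e-2)
        first = None
        for _ in range(30):
            opt.zero_grad()
            loss = training_loss(m.forward(hist, win, extras), None, label)
            if first is None:
                first = float(loss.data)
            loss.backward()
            opt.step()
        assert float(loss.data) < 0.5 * first
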