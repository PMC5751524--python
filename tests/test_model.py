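"""The peephole Bi-LSTM network: step equations, channel runs, head, gradients."""

import math

import numpy as np
import pytest

from ddi_dlstm.config import HyperParams
from ddi_dlstm.corpus_io import CLASSES, Vocabulary
from ddi_dlstm.errors import ContractError
from ddi_dlstm.features import ChannelIndices
from ddi_dlstm.model import (
    RelationClassifier,
    init_lstm_params,
    lstm_step,
    predict,
    run_channel,
)
from ddi_dlstm.training import cross_entropy


def scalar_lstm_oracle(xs, p):
    """Independent per-component loop implementation of the step equations."""
    H = len(p["b_i"])
    D = len(xs[0])
    h = [0.0] * H
    c = [0.0] * H
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    outs = []
    for x in xs:
        i_g, f_g, g_g, o_g, c_new = [0.0] * H, [0.0] * H, [0.0] * H, [0.0] * H, [0.0] * H
        for u in range(H):
            ai = p["b_i"][u] + sum(p["W_xi"][u][d] * x[d] for d in range(D)) \
                + sum(p["W_hi"][u][v] * h[v] for v in range(H)) + p["w_ci"][u] * c[u]
            af = p["b_f"][u] + sum(p["W_xf"][u][d] * x[d] for d in range(D)) \
                + sum(p["W_hf"][u][v] * h[v] for v in range(H)) + p["w_cf"][u] * c[u]
            ag = p["b_c"][u] + sum(p["W_xc"][u][d] * x[d] for d in range(D)) \
                + sum(p["W_hc"][u][v] * h[v] for v in range(H))
            i_g[u], f_g[u], g_g[u] = sig(ai), sig(af), math.tanh(ag)
            c_new[u] = f_g[u] * c[u] + i_g[u] * g_g[u]
        for u in range(H):
            ao = p["b_o"][u] + sum(p["W_xo"][u][d] * x[d] for d in range(D)) \
                + sum(p["W_ho"][u][v] * h[v] for v in range(H)) + p["w_co"][u] * c_new[u]
            o_g[u] = sig(ao)
        c = c_new
        h = [o_g[u] * math.tanh(c[u]) for u in range(H)]
        outs.append(list(h))
    return outs


def random_feats(rng, vocab, n, channels=("linear", "dfs", "bfs"), max_len=6):
    out = []
    for _ in range(n):
        L = int(rng.integers(2, max_len + 1))
        ids = rng.integers(0, len(vocab), size=L)
        chans = {}
        for ch in channels:
            order = np.arange(L) if ch == "linear" else rng.permutation(L)
            chans[ch] = ChannelIndices(ch, order,
                                       rng.integers(-5, 6, L), rng.integers(-5, 6, L))
        out.append((ids, chans))
    return out


class TestLSTMStep:
    def test_zero_params_zero_state_gives_zero(self):
        p = {k: np.zeros_like(v) for k, v in
             init_lstm_params(np.random.default_rng(0), 3, 4).items()}
        h, c = lstm_step(np.ones(3), np.zeros(4), np.zeros(4), p)
        assert not h.any() and not c.any()

    def test_saturated_forget_gate_preserves_cell(self):
        p = {k: np.zeros_like(v) for k, v in
             init_lstm_params(np.random.default_rng(0), 2, 3).items()}
        p["b_f"] += 50.0    # forget gate ~ 1
        p["b_i"] -= 50.0    # input gate ~ 0
        c_prev = np.array([0.3, -0.7, 1.2])
        _, c = lstm_step(np.ones(2), np.zeros(3), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            H, D, T = int(rng.integers(2, 5)), int(rng.integers(2, 5)), 4
            p = init_lstm_params(rng, D, H)
            for k in p:
                p[k] = rng.normal(scale=0.5, size=p[k].shape)
            xs = rng.normal(size=(T, D))
            expect = scalar_lstm_oracle([list(x) for x in xs],
                                        {k: v.tolist() for k, v in p.items()})
            h = np.zeros(H)
            c = np.zeros(H)
            for t in range(T):
                h, c = lstm_step(xs[t], h, c, p)
                np.testing.assert_allclose(h, expect[t], atol=1e-10)

    def test_gate_outputs_bound_hidden_state(self):
        rng = np.random.default_rng(1)
        p = init_lstm_params(rng, 3, 5)
        h, c = lstm_step(rng.normal(size=3) * 10, np.zeros(5), np.zeros(5), p)
        assert np.all(np.abs(h) < 1.0)  # |h| = |o * tanh(c)| < 1


class TestRunChannel:
    def test_single_step_pooling_identity(self):
        rng = np.random.default_rng(3)
        pf = init_lstm_params(rng, 4, 6)
        pb = init_lstm_params(rng, 4, 6)
        out = run_channel(rng.normal(size=(1, 4)), pf, pb)
        np.testing.assert_array_equal(out.pooled, out.z[0])

    def test_palindrome_symmetry_with_tied_params(self):
        rng = np.random.default_rng(4)
        p = init_lstm_params(rng, 3, 5)
        half = rng.normal(size=(3, 3))
        x = np.concatenate([half, half[::-1]], axis=0)  # palindromic sequence
        out = run_channel(x, p, p)
        np.testing.assert_allclose(out.h_forward, out.h_backward[::-1], atol=1e-12)

    def test_z_is_mean_and_pool_dominates(self):
        rng = np.random.default_rng(5)
        out = run_channel(rng.normal(size=(7, 3)),
                          init_lstm_params(rng, 3, 4), init_lstm_params(rng, 3, 4))
        np.testing.assert_allclose(out.z, (out.h_forward + out.h_backward) / 2)
        assert np.all(out.pooled[None, :] >= out.z - 1e-15)

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(6)
        p = init_lstm_params(rng, 3, 4)
        with pytest.raises(ContractError):
            run_channel(np.zeros((0, 3)), p, p)


class TestPredict:
    def test_one_hot(self):
        v = np.zeros(5)
        v[3] = 1.0
        assert predict(v) == CLASSES[3]

    def test_uniform_tie_breaks_to_first_class(self):
        assert predict(np.full(5, 0.2)) == "Advice"

    def test_agrees_with_scan_max(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.random(5)
            v /= v.sum()
            best, arg = -1.0, 0
            for i, x in enumerate(v):
                if x > best:
                    best, arg = x, i
            assert predict(v) == CLASSES[arg]


@pytest.fixture
def small_model():
    vocab = Vocabulary([f"w{i}" for i in range(10)])
    hp = HyperParams(dw=5, dp=4, num=6, rho=1.0, seed=0)
    return RelationClassifier(vocab, hp, np.random.default_rng(8)), hp


class TestForward:
    def test_zero_head_gives_uniform(self, small_model):
        model, _ = small_model
        model.params["W_s"][:] = 0
        model.params["b_s"][:] = 0
        feats = random_feats(np.random.default_rng(9), model.vocab, 3)
        probs = model.predict_proba(feats)
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_probabilities_normalized(self, small_model):
        model, _ = small_model
        feats = random_feats(np.random.default_rng(10), model.vocab, 40)
        probs = model.predict_proba(feats)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0)

    def test_padding_invariance(self, small_model):
        """A padded batch scores each instance exactly as a singleton batch."""
        model, _ = small_model
        feats = random_feats(np.random.default_rng(11), model.vocab, 8, max_len=9)
        together = model.predict_proba(feats)
        separate = np.concatenate([model.predict_proba([f]) for f in feats])
        np.testing.assert_allclose(together, separate, atol=1e-12)

    def test_tree_channel_sensitivity_and_linear_independence(self, small_model):
        model, hp = small_model
        rng = np.random.default_rng(12)
        [(ids, chans)] = random_feats(rng, model.vocab, 1, max_len=6)
        shuffled = dict(chans)
        perm = rng.permutation(len(chans["dfs"].order))
        d = chans["dfs"]
        shuffled["dfs"] = ChannelIndices("dfs", d.order[perm], d.f1[perm], d.f2[perm])
        p1 = model.predict_proba([(ids, chans)])
        p2 = model.predict_proba([(ids, shuffled)])
        assert not np.allclose(p1, p2)  # DFS channel sees its order
        lin_model = RelationClassifier(
            model.vocab, HyperParams(dw=5, dp=4, num=6, rho=1.0, channels=("linear",)),
            np.random.default_rng(8),
        )
        np.testing.assert_allclose(lin_model.predict_proba([(ids, chans)]),
                                   lin_model.predict_proba([(ids, shuffled)]))

    def test_head_width_is_three_hidden_not_six(self, small_model):
        model, hp = small_model
        assert model.params["W_s"].shape == (5, 3 * hp.num)


class TestGradients:
    def test_backprop_matches_finite_differences(self, small_model):
        model, _ = small_model
        rng = np.random.default_rng(13)
        feats = random_feats(rng, model.vocab, 4)
        y = np.array([0, 2, 4, 1])
        batch = model.make_batch(feats)
        _, cache = model.forward_batch(batch)
        grads = model.backward_batch(cache, y)
        eps = 1e-6
        for name in ("E", "W_s", "b_s", "linear.f.W_xi", "dfs.b.W_hf",
                     "bfs.f.w_co", "linear.b.b_c", "dfs.f.w_ci"):
            flat = model.params[name].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                p1, _ = model.forward_batch(batch)
                flat[i] = orig - eps
                p2, _ = model.forward_batch(batch)
                flat[i] = orig
                num = (cross_entropy(p1, y) - cross_entropy(p2, y)) / (2 * eps)
                assert abs(num - grads[name].ravel()[i]) < 1e-7, name


class TestCheckpoint:
    def test_save_load_roundtrip(self, small_model, tmp_path):
        model, _ = small_model
        feats = random_feats(np.random.default_rng(14), model.vocab, 5)
        before = model.predict_proba(feats)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = RelationClassifier.load(path)
        assert loaded.vocab.content_hash() == model.vocab.content_hash()
        np.testing.assert_array_equal(loaded.predict_proba(feats), before)
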