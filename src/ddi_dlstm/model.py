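"""Three-channel bidirectional peephole-LSTM relation classifier.

Each channel (linear / DFS / BFS token order) runs a forward and a backward
LSTM with peephole connections; per position the two hidden states are
*averaged*, the averaged sequence is max-pooled over time, the pooled channel
vectors are concatenated, passed through tanh and (during training) dropout,
and projected to a 5-way softmax.

One LSTM step, with sigmoid gates and elementwise products:

    i_t = s(W_xi x_t + W_hi h_{t-1} + w_ci . c_{t-1} + b_i)
    f_t = s(W_xf x_t + W_hf h_{t-1} + w_cf . c_{t-1} + b_f)
    g_t = tanh(W_xc x_t + W_hc h_{t-1} + b_c)          (candidate)
    c_t = f_t . c_{t-1} + i_t . g_t
    o_t = s(W_xo x_t + W_ho h_{t-1} + w_co . c_t + b_o)  (peephole on current cell)
    h_t = o_t . tanh(c_t)

Peepholes are diagonal by default (vector weights); set
``full_peepholes=True`` for full matrices.  Everything is plain numpy with
hand-derived backpropagation-through-time gradients; a finite-difference test
pins the gradients down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import HyperParams
from .corpus_io import CLASSES, Vocabulary
from .errors import ContractError, DDIError
from .features import ChannelIndices, encode_distances

GATES = ("i", "f", "c", "o")  # input, forget, candidate, output


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Parameters

def init_lstm_params(rng: np.random.Generator, input_dim: int, hidden: int,
                     full_peepholes: bool = False) -> dict[str, np.ndarray]:
    """Uniform fan-in-scaled initialization of one LSTM block."""
    p = {}
    sx = 1.0 / np.sqrt(input_dim)
    sh = 1.0 / np.sqrt(hidden)
    for g in GATES:
        p[f"W_x{g}"] = rng.uniform(-sx, sx, size=(hidden, input_dim))
        p[f"W_h{g}"] = rng.uniform(-sh, sh, size=(hidden, hidden))
        p[f"b_{g}"] = np.zeros(hidden)
    for g in ("i", "f", "o"):
        shape = (hidden, hidden) if full_peepholes else (hidden,)
        p[f"w_c{g}"] = rng.uniform(-sh, sh, size=shape)
    return p


def _peep(w: np.ndarray, c: np.ndarray) -> np.ndarray:
    return c @ w.T if w.ndim == 2 else c * w


def _peep_back(w: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Gradient of a peephole term w.r.t. the cell vector."""
    return da @ w if w.ndim == 2 else da * w


def _peep_grad(w: np.ndarray, da: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the peephole weight itself."""
    return da.T @ c if w.ndim == 2 else (da * c).sum(axis=0)


# ---------------------------------------------------------------------------
# Single step (the contract-level operation; batched over leading axis)

def lstm_step(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """One peephole-LSTM step; returns (h_t, c_t)."""
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(h_prev))):
        raise DDIError("non-finite input to lstm_step")
    i = sigmoid(x @ p["W_xi"].T + h_prev @ p["W_hi"].T + _peep(p["w_ci"], c_prev) + p["b_i"])
    f = sigmoid(x @ p["W_xf"].T + h_prev @ p["W_hf"].T + _peep(p["w_cf"], c_prev) + p["b_f"])
    g = np.tanh(x @ p["W_xc"].T + h_prev @ p["W_hc"].T + p["b_c"])
    c = f * c_prev + i * g
    o = sigmoid(x @ p["W_xo"].T + h_prev @ p["W_ho"].T + _peep(p["w_co"], c) + p["b_o"])
    h = o * np.tanh(c)
    return h, c


def _lstm_step_cached(x, h_prev, c_prev, p):
    i = sigmoid(x @ p["W_xi"].T + h_prev @ p["W_hi"].T + _peep(p["w_ci"], c_prev) + p["b_i"])
    f = sigmoid(x @ p["W_xf"].T + h_prev @ p["W_hf"].T + _peep(p["w_cf"], c_prev) + p["b_f"])
    g = np.tanh(x @ p["W_xc"].T + h_prev @ p["W_hc"].T + p["b_c"])
    c = f * c_prev + i * g
    o = sigmoid(x @ p["W_xo"].T + h_prev @ p["W_ho"].T + _peep(p["w_co"], c) + p["b_o"])
    tc = np.tanh(c)
    h = o * tc
    cache = (x, h_prev, c_prev, i, f, g, o, c, tc)
    return h, c, cache


def run_lstm(X: np.ndarray, mask: np.ndarray, p: dict[str, np.ndarray]):
    """Run an LSTM over a padded batch.

    X: (B, T, D); mask: (B, T) with 1 on valid positions (right-padded).
    At masked positions the state passes through unchanged.  Returns the
    hidden sequence H (B, T, H) and the step caches for backprop.
    """
    B, T, _ = X.shape
    H = p["b_i"].shape[-1] if p["b_i"].ndim == 1 else p["b_i"].shape[-1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.zeros((B, T, H))
    caches = []
    for t in range(T):
        m = mask[:, t][:, None]
        h_new, c_new, cache = _lstm_step_cached(X[:, t], h, c, p)
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        hs[:, t] = h
        caches.append((cache, m))
    return hs, caches


def backward_lstm(dH: np.ndarray, caches, p: dict[str, np.ndarray]):
    """BPTT through :func:`run_lstm`.

    dH: (B, T, H) gradient w.r.t. each (post-mask) hidden output.
    Returns (param gradient dict, dX (B, T, D)).
    """
    B, T, Hd = dH.shape
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dX = np.zeros((B, T, caches[0][0][0].shape[-1]))
    dh = np.zeros((B, Hd))
    dc = np.zeros((B, Hd))
    for t in range(T - 1, -1, -1):
        (x, h_prev, c_prev, i, f, g, o, c, tc), m = caches[t]
        dh = dh + dH[:, t]
        dh_new = m * dh
        dc_new = m * dc
        dh_pass = (1 - m) * dh
        dc_pass = (1 - m) * dc

        do = dh_new * tc
        dao = do * o * (1 - o)
        dcell = dc_new + dh_new * o * (1 - tc * tc) + _peep_back(p["w_co"], dao)
        di = dcell * g
        dai = di * i * (1 - i)
        df = dcell * c_prev
        daf = df * f * (1 - f)
        dg = dcell * i
        dag = dg * (1 - g * g)

        grads["W_xi"] += dai.T @ x
        grads["W_xf"] += daf.T @ x
        grads["W_xc"] += dag.T @ x
        grads["W_xo"] += dao.T @ x
        grads["W_hi"] += dai.T @ h_prev
        grads["W_hf"] += daf.T @ h_prev
        grads["W_hc"] += dag.T @ h_prev
        grads["W_ho"] += dao.T @ h_prev
        grads["b_i"] += dai.sum(axis=0)
        grads["b_f"] += daf.sum(axis=0)
        grads["b_c"] += dag.sum(axis=0)
        grads["b_o"] += dao.sum(axis=0)
        grads["w_ci"] += _peep_grad(p["w_ci"], dai, c_prev)
        grads["w_cf"] += _peep_grad(p["w_cf"], daf, c_prev)
        grads["w_co"] += _peep_grad(p["w_co"], dao, c)

        dX[:, t] = dai @ p["W_xi"] + daf @ p["W_xf"] + dag @ p["W_xc"] + dao @ p["W_xo"]
        dh = dai @ p["W_hi"] + daf @ p["W_hf"] + dag @ p["W_hc"] + dao @ p["W_ho"] + dh_pass
        dc = dcell * f + _peep_back(p["w_ci"], dai) + _peep_back(p["w_cf"], daf) + dc_pass
    return grads, dX


# ---------------------------------------------------------------------------
# Bi-LSTM channel

@dataclass
class BiChannelOutput:
    """Aligned forward/backward hidden sequences, their average, and the pool."""

    h_forward: np.ndarray   # (m, H)
    h_backward: np.ndarray  # (m, H), aligned by token position
    z: np.ndarray           # (m, H), (h_f + h_b) / 2
    pooled: np.ndarray      # (H,), componentwise max over positions


def run_channel(vectors: np.ndarray, params_f: dict, params_b: dict) -> BiChannelOutput:
    """Run one Bi-LSTM channel over a single (unpadded) sequence.

    The backward pass consumes the reversed sequence and its outputs are
    re-reversed so ``h_backward[t]`` aligns with position ``t``.
    """
    m = vectors.shape[0]
    if m == 0:
        raise ContractError("run_channel requires at least one token")
    X = vectors[None, :, :]
    mask = np.ones((1, m))
    hf, _ = run_lstm(X, mask, params_f)
    hb_rev, _ = run_lstm(X[:, ::-1], mask, params_b)
    hb = hb_rev[:, ::-1]
    z = (hf[0] + hb[0]) / 2.0
    return BiChannelOutput(hf[0], hb[0], z, z.max(axis=0))


def predict(probs: np.ndarray) -> str:
    """Argmax label; ties resolved by the fixed class order."""
    probs = np.asarray(probs)
    if probs.ndim != 1 or probs.shape[0] != len(CLASSES) or not np.isclose(probs.sum(), 1.0, atol=1e-4):
        raise ContractError("predict expects one probability vector over the 5 classes")
    return CLASSES[int(np.argmax(probs))]


# ---------------------------------------------------------------------------
# Full classifier

class RelationClassifier:
    """The assembled network: embeddings, 2 LSTMs per channel, softmax head.

    Parameters live in a flat name->array dict (``self.params``) so the
    optimizer and parameter averaging can treat them uniformly.
    """

    def __init__(
        self,
        vocab: Vocabulary,
        cfg: HyperParams,
        rng: np.random.Generator,
        embeddings: np.ndarray | None = None,
    ):
        self.vocab = vocab
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        if embeddings is None:
            embeddings = rng.uniform(-1.0, 1.0, size=(len(vocab), cfg.dw))
        if embeddings.shape != (len(vocab), cfg.dw):
            raise ContractError(
                f"embedding matrix {embeddings.shape} does not match "
                f"(|vocab|={len(vocab)}, dw={cfg.dw})"
            )
        self.params["E"] = embeddings.astype(float).copy()
        for ch in cfg.channels:
            for d in ("f", "b"):
                block = init_lstm_params(rng, cfg.input_dim, cfg.num, cfg.full_peepholes)
                for k, v in block.items():
                    self.params[f"{ch}.{d}.{k}"] = v
        head_dim = cfg.num * len(cfg.channels)
        sh = 1.0 / np.sqrt(head_dim)
        self.params["W_s"] = rng.uniform(-sh, sh, size=(len(CLASSES), head_dim))
        self.params["b_s"] = np.zeros(len(CLASSES))

    # -- batching ----------------------------------------------------------

    def make_batch(self, feats: Sequence[tuple[np.ndarray, dict[str, ChannelIndices]]]):
        """Pad a list of (token_id array, channel dict) into batch arrays."""
        B = len(feats)
        lengths = np.array([len(ids) for ids, _ in feats])
        T = int(lengths.max())
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
        batch = {"mask": mask, "lengths": lengths, "channels": {}}
        for ch in self.cfg.channels:
            tok = np.zeros((B, T), dtype=int)
            f1 = np.zeros((B, T), dtype=int)
            f2 = np.zeros((B, T), dtype=int)
            for b, (ids, chans) in enumerate(feats):
                ci = chans[ch]
                tok[b, : lengths[b]] = ids[ci.order]
                f1[b, : lengths[b]] = ci.f1
                f2[b, : lengths[b]] = ci.f2
            batch["channels"][ch] = (tok, f1, f2)
        return batch

    def _block(self, ch: str, d: str) -> dict[str, np.ndarray]:
        prefix = f"{ch}.{d}."
        return {k[len(prefix):]: v for k, v in self.params.items() if k.startswith(prefix)}

    def forward_batch(self, batch, train: bool = False, rng: np.random.Generator | None = None):
        """Forward pass; returns (probs (B, 5), cache for backprop)."""
        mask = batch["mask"]
        lengths = batch["lengths"]
        B, T = mask.shape
        rev = np.where(
            np.arange(T)[None, :] < lengths[:, None],
            lengths[:, None] - 1 - np.arange(T)[None, :],
            np.arange(T)[None, :],
        )
        cache = {"mask": mask, "rev": rev, "channels": {}}
        pooled = []
        for ch in self.cfg.channels:
            tok, f1, f2 = batch["channels"][ch]
            X = np.concatenate(
                [self.params["E"][tok],
                 encode_distances(f1, self.cfg.dp),
                 encode_distances(f2, self.cfg.dp)],
                axis=-1,
            )
            Xr = np.take_along_axis(X, rev[:, :, None], axis=1)
            hf, cf = run_lstm(X, mask, self._block(ch, "f"))
            hbr, cb = run_lstm(Xr, mask, self._block(ch, "b"))
            hb = np.take_along_axis(hbr, rev[:, :, None], axis=1)
            z = (hf + hb) / 2.0
            zm = np.where(mask[:, :, None] > 0, z, -np.inf)
            arg = zm.argmax(axis=1)                       # (B, H)
            pool = np.take_along_axis(zm, arg[:, None, :], axis=1)[:, 0, :]
            pooled.append(pool)
            cache["channels"][ch] = {"tok": tok, "cf": cf, "cb": cb, "arg": arg}
        Z = np.concatenate(pooled, axis=1)
        hs = np.tanh(Z)
        if train:
            q = self.cfg.keep_prob
            if rng is None:
                raise ContractError("training-mode forward needs an rng for dropout")
            drop = (rng.random(hs.shape) < q).astype(float) / q if q < 1.0 else np.ones_like(hs)
        else:
            drop = np.ones_like(hs)
        hd = hs * drop
        logits = hd @ self.params["W_s"].T + self.params["b_s"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache.update(hs=hs, hd=hd, drop=drop, probs=probs)
        return probs, cache

    def backward_batch(self, cache, y_idx: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the mean cross-entropy w.r.t. every parameter."""
        probs = cache["probs"]
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["W_s"] = dlogits.T @ cache["hd"]
        grads["b_s"] = dlogits.sum(axis=0)
        dhd = dlogits @ self.params["W_s"]
        dhs = dhd * cache["drop"]
        dZ = dhs * (1 - cache["hs"] ** 2)
        H = self.cfg.num
        mask, rev = cache["mask"], cache["rev"]
        B_, T = mask.shape
        for k, ch in enumerate(self.cfg.channels):
            cc = cache["channels"][ch]
            dpool = dZ[:, k * H : (k + 1) * H]
            dz = np.zeros((B_, T, H))
            np.put_along_axis(dz, cc["arg"][:, None, :], dpool[:, None, :], axis=1)
            dh = dz / 2.0
            gf, dXf = backward_lstm(dh, cc["cf"], self._block(ch, "f"))
            dhr = np.take_along_axis(dh, rev[:, :, None], axis=1)
            gb, dXr = backward_lstm(dhr, cc["cb"], self._block(ch, "b"))
            dX = dXf + np.take_along_axis(dXr, rev[:, :, None], axis=1)
            for name, g in gf.items():
                grads[f"{ch}.f.{name}"] = g
            for name, g in gb.items():
                grads[f"{ch}.b.{name}"] = g
            dword = dX[:, :, : self.cfg.dw] * mask[:, :, None]
            np.add.at(grads["E"], cc["tok"].ravel(), dword.reshape(-1, self.cfg.dw))
        return grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, feats, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(feats), batch_size):
            batch = self.make_batch(feats[i : i + batch_size])
            probs, _ = self.forward_batch(batch, train=False)
            out.append(probs)
        return np.concatenate(out, axis=0) if out else np.zeros((0, len(CLASSES)))

    def predict_labels(self, feats, batch_size: int = 256) -> list[str]:
        probs = self.predict_proba(feats, batch_size)
        return [CLASSES[i] for i in probs.argmax(axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file archive: npz with a JSON header describing the config."""
        header = json.dumps({
            "config": self.cfg.to_dict(),
            "vocab": self.vocab.tokens(),
            "vocab_hash": self.vocab.content_hash(),
            "classes": list(CLASSES),
        })
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "RelationClassifier":
        data = np.load(path)
        header = json.loads(bytes(data["__header__"]).decode())
        cfg_d = header["config"]
        cfg_d["channels"] = tuple(cfg_d["channels"])
        cfg = HyperParams(**cfg_d)
        vocab = Vocabulary()
        for tok in header["vocab"]:
            vocab.add(tok)
        obj = cls(vocab, cfg, np.random.default_rng(0))
        for k in obj.params:
            obj.params[k] = data[k]
        return obj
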