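"""Imbalance-aware training loop.

Per epoch the training set is re-sampled: Negative instances are
undersampled (one draw of floor(alpha*|Neg|) without replacement, fresh each
epoch so successive epochs see different negatives), Int instances are
oversampled (K independent draws of floor(beta*|Int|) without replacement,
concatenated, so duplicates across draws are intended), and the other
classes pass through unchanged.  Optimization is Adam on the mean
cross-entropy plus L2 on the weights, with global-norm gradient clipping and
a running arithmetic average of the parameters (used at evaluation time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import HyperParams
from .corpus_io import CLASSES, Vocabulary
from .errors import ContractError, TrainingDivergence
from .features import build_tree, channel_indices
from .model import RelationClassifier
from .preprocess import CandidateInstance
from . import evaluation

_CLASS_IDX = {c: i for i, c in enumerate(CLASSES)}

#: parameter-name predicate for L2 (weight matrices and peepholes; biases and
#: the embedding table are not penalized)
def _is_weight(name: str) -> bool:
    short = name.rsplit(".", 1)[-1]
    return short.startswith(("W_", "w_c"))


def sample_epoch(
    train: list[CandidateInstance], cfg: HyperParams, epoch: int
) -> list[CandidateInstance]:
    """Build one epoch's training list (shuffled; contents never altered)."""
    rng = np.random.default_rng(cfg.seed + epoch)
    by_class: dict[str, list[CandidateInstance]] = {c: [] for c in CLASSES}
    for inst in train:
        by_class[inst.label].append(inst)
    out: list[CandidateInstance] = []
    for c in ("Advice", "Effect", "Mechanism"):
        out.extend(by_class[c])
    neg = by_class["Negative"]
    if neg:
        k = math.floor(cfg.alpha * len(neg))
        idx = rng.choice(len(neg), size=k, replace=False)
        out.extend(neg[i] for i in idx)
    ints = by_class["Int"]
    if ints:
        k = math.floor(cfg.beta * len(ints))
        for _ in range(cfg.K):
            idx = rng.choice(len(ints), size=k, replace=False)
            out.extend(ints[i] for i in idx)
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    """Mean cross-entropy with probability clamping at 1e-12."""
    p = np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-12, 1.0)
    return float(-np.log(p).mean())


def loss(probs: np.ndarray, y_idx: np.ndarray, params: dict[str, np.ndarray],
         l2: float) -> float:
    """Cross-entropy plus ``l2 * sum of squared weight entries``."""
    reg = sum(float((v ** 2).sum()) for k, v in params.items() if _is_weight(k))
    return cross_entropy(probs, y_idx) + l2 * reg


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    dev_micro_f: list[float] = field(default_factory=list)
    sampled_counts: list[dict[str, int]] = field(default_factory=list)
    best_epoch: int = -1


def featurize(
    instances: list[CandidateInstance], vocab: Vocabulary
) -> list[tuple[np.ndarray, dict]]:
    """Precompute token ids and channel index content for each instance."""
    feats = []
    for inst in instances:
        if inst.parse is None:
            raise ContractError(
                f"{inst.sentence_id}/{inst.pair_id}: instance has no parse"
            )
        tree = build_tree(inst.parse, inst.sentence_id)
        ids = np.array([vocab[t] for t in inst.tokens])
        feats.append((ids, channel_indices(inst, tree)))
    return feats


def build_vocabulary(instances: list[CandidateInstance]) -> Vocabulary:
    vocab = Vocabulary()
    for inst in instances:
        for tok in inst.tokens:
            vocab.add(tok)
    return vocab


def train(
    train_instances: list[CandidateInstance],
    model: RelationClassifier,
    cfg: HyperParams,
    dev_instances: list[CandidateInstance] | None = None,
) -> TrainHistory:
    """Fit the classifier; returns the history.  When parameter averaging is
    enabled the model ends up holding the running average of its weights
    (the raw final weights are kept under ``model.raw_params``)."""
    if not train_instances:
        raise ContractError("empty training set")
    if dev_instances is None and cfg.dev_fraction > 0:
        # split by sentence so pairs from one sentence stay together
        sids = sorted({i.sentence_id for i in train_instances})
        rng = np.random.default_rng(cfg.seed)
        rng.shuffle(sids)
        n_dev = max(1, int(len(sids) * cfg.dev_fraction))
        dev_ids = set(sids[:n_dev])
        dev_instances = [i for i in train_instances if i.sentence_id in dev_ids]
        train_instances = [i for i in train_instances if i.sentence_id not in dev_ids]

    feat_cache: dict[int, tuple] = {}

    def feats_for(insts):
        missing = [i for i in insts if id(i) not in feat_cache]
        if missing:
            for inst, f in zip(missing, featurize(missing, model.vocab)):
                feat_cache[id(inst)] = f
        return [feat_cache[id(i)] for i in insts]

    feats_for(train_instances)
    dev_feats = feats_for(dev_instances) if dev_instances else None
    dev_gold = [i.label for i in dev_instances] if dev_instances else None

    opt = Adam(model.params, cfg.la)
    avg = {k: v.copy() for k, v in model.params.items()}
    n_updates = 1
    history = TrainHistory()
    drop_rng = np.random.default_rng(cfg.seed + 7919)
    best_f, best_params, patience_left = -1.0, None, cfg.patience

    for epoch in range(cfg.max_epochs):
        sampled = sample_epoch(train_instances, cfg, epoch)
        counts = {c: 0 for c in CLASSES}
        for inst in sampled:
            counts[inst.label] += 1
        history.sampled_counts.append(counts)
        sfeats = feats_for(sampled)
        labels = np.array([_CLASS_IDX[i.label] for i in sampled])
        losses = []
        for start in range(0, len(sampled), cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            batch = model.make_batch(sfeats[sl])
            probs, cache = model.forward_batch(batch, train=True, rng=drop_rng)
            y = labels[sl]
            batch_loss = loss(probs, y, model.params, cfg.l2)
            if not math.isfinite(batch_loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            grads = model.backward_batch(cache, y)
            if cfg.l2 > 0:
                for k in grads:
                    if _is_weight(k):
                        grads[k] += 2.0 * cfg.l2 * model.params[k]
            clip_global_norm(grads, cfg.clip_norm)
            opt.step(model.params, grads)
            n_updates += 1
            if cfg.parameter_averaging:
                w = 1.0 / n_updates
                for k, v in model.params.items():
                    avg[k] += w * (v - avg[k])
            losses.append(batch_loss)
        history.epoch_loss.append(float(np.mean(losses)) if losses else 0.0)

        if dev_feats:
            eval_params = avg if cfg.parameter_averaging else model.params
            micro_f = _dev_micro_f(model, eval_params, dev_feats, dev_gold)
            history.dev_micro_f.append(micro_f)
            if micro_f > best_f:
                best_f = micro_f
                best_params = {k: v.copy() for k, v in eval_params.items()}
                history.best_epoch = epoch
                patience_left = cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    model.raw_params = model.params
    if dev_feats and best_params is not None:
        model.params = best_params
    elif cfg.parameter_averaging:
        model.params = avg
    return history


def _dev_micro_f(model, params, dev_feats, dev_gold) -> float:
    saved = model.params
    model.params = params
    try:
        pred = model.predict_labels(dev_feats)
    finally:
        model.params = saved
    return evaluation.score(dev_gold, pred).micro_f
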