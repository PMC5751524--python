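"""Channel construction: linear order with relative token distances, and
DFS/BFS dependency-tree orders with depth differences.

Each token in a channel is represented by its word embedding concatenated
with two encoded integers.  For the linear channel the integers are signed
token distances to DRUG_1 and DRUG_2 (``D = drug_position - token_position``,
so a word left of both drugs gets positive distances).  For the tree channels
they are depth differences ``d1 = L - L1`` and ``d2 = L - L2`` where ``L`` is
the node's edge count to the root.  Integers are encoded as 10-bit
sign-magnitude binary vectors (bit 0 = sign, bits 1-9 = |v| clamped to 511,
most significant first).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .corpus_io import DRUG_1, DRUG_2, Parse, Vocabulary
from .errors import ContractError, TreeError
from .preprocess import CandidateInstance

CHANNELS = ("linear", "dfs", "bfs")


@dataclass(frozen=True)
class DepTree:
    """Single-rooted dependency tree over sentence tokens (0-based indices)."""

    head: tuple[int, ...]   # parent index; -1 for the root
    rel: tuple[str, ...]
    root_index: int

    def __len__(self) -> int:
        return len(self.head)

    def children(self, i: int) -> list[int]:
        return [j for j, h in enumerate(self.head) if h == i]

    def depths(self) -> np.ndarray:
        """Edge count to the root for every node."""
        d = np.full(len(self.head), -1, dtype=int)
        d[self.root_index] = 0
        queue = deque([self.root_index])
        kids: dict[int, list[int]] = {}
        for j, h in enumerate(self.head):
            if h >= 0:
                kids.setdefault(h, []).append(j)
        while queue:
            u = queue.popleft()
            for v in kids.get(u, ()):  # token order preserved
                d[v] = d[u] + 1
                queue.append(v)
        return d


def build_tree(parse: Parse, sentence_id: str = "") -> DepTree:
    """Validate heads and build a :class:`DepTree`.

    Fragmented parses (several heads of 0) are repaired by attaching every
    extra root to the first one with a synthetic "dep" relation; cycles or
    unreachable nodes raise :class:`TreeError`.
    """
    n = len(parse)
    if n == 0:
        raise TreeError(f"sentence {sentence_id or parse.sent_id}: empty parse")
    heads = [h - 1 for h in parse.heads]  # to 0-based; root becomes -1
    rels = list(parse.rels)
    roots = [i for i, h in enumerate(heads) if h == -1]
    if not roots:
        raise TreeError(f"sentence {sentence_id or parse.sent_id}: no root")
    root = roots[0]
    for extra in roots[1:]:
        heads[extra] = root
        rels[extra] = "dep"
    tree = DepTree(tuple(heads), tuple(rels), root)
    if np.count_nonzero(tree.depths() >= 0) != n:
        raise TreeError(
            f"sentence {sentence_id or parse.sent_id}: cyclic or disconnected heads"
        )
    return tree


# ---------------------------------------------------------------------------
# Per-token integer features

def distance_features(instance: CandidateInstance) -> list[tuple[int, int]]:
    """Signed token distances (D1, D2) from each position to the drug pair."""
    i1, i2 = instance.drug1_index, instance.drug2_index
    if instance.tokens[i1] != DRUG_1 or instance.tokens[i2] != DRUG_2:
        raise ContractError(
            f"{instance.sentence_id}/{instance.pair_id}: drug indices do not point "
            "at placeholder tokens"
        )
    return [(i1 - p, i2 - p) for p in range(len(instance.tokens))]


def depth_features(tree: DepTree, instance: CandidateInstance) -> list[tuple[int, int]]:
    """Depth differences (L - L1, L - L2) for each token, in token order."""
    depths = tree.depths()
    l1 = depths[instance.drug1_index]
    l2 = depths[instance.drug2_index]
    return [(int(d - l1), int(d - l2)) for d in depths]


def dfs_order(tree: DepTree) -> list[int]:
    """Preorder depth-first traversal; children visited in token order."""
    kids: dict[int, list[int]] = {}
    for j, h in enumerate(tree.head):
        if h >= 0:
            kids.setdefault(h, []).append(j)
    order: list[int] = []
    stack = [tree.root_index]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(kids.get(u, ())))
    return order


def bfs_order(tree: DepTree) -> list[int]:
    """Level-order traversal; within a level, nodes in token order of discovery."""
    kids: dict[int, list[int]] = {}
    for j, h in enumerate(tree.head):
        if h >= 0:
            kids.setdefault(h, []).append(j)
    order: list[int] = []
    queue = deque([tree.root_index])
    while queue:
        u = queue.popleft()
        order.append(u)
        queue.extend(kids.get(u, ()))
    return order


# ---------------------------------------------------------------------------
# Distance encoding

def encode_distance(v: int, dp: int = 10) -> np.ndarray:
    """Sign-magnitude binary code: bit 0 = 1 iff v < 0, then |v| clamped to
    2**(dp-1) - 1, most significant bit first.  encode_distance(0) is all
    zeros."""
    out = np.zeros(dp, dtype=float)
    if v < 0:
        out[0] = 1.0
    mag = min(abs(int(v)), (1 << (dp - 1)) - 1)
    for k in range(dp - 1):
        out[1 + k] = (mag >> (dp - 2 - k)) & 1
    return out


def encode_distances(values: np.ndarray, dp: int = 10) -> np.ndarray:
    """Vectorized :func:`encode_distance` over an integer array; appends a
    trailing axis of size ``dp``."""
    values = np.asarray(values)
    sign = (values < 0).astype(float)[..., None]
    mag = np.minimum(np.abs(values), (1 << (dp - 1)) - 1)
    shifts = np.arange(dp - 2, -1, -1)
    bits = ((mag[..., None] >> shifts) & 1).astype(float)
    return np.concatenate([sign, bits], axis=-1)


# ---------------------------------------------------------------------------
# Channel assembly

@dataclass
class ChannelIndices:
    """Integer-level channel content: token order and the two feature ints.

    ``order[k]`` is the original token index visited at step k; ``f1``/``f2``
    are that token's two integer features (distances for the linear channel,
    depth differences for the tree channels).
    """

    channel: str
    order: np.ndarray
    f1: np.ndarray
    f2: np.ndarray


@dataclass
class ChannelSequence:
    """Materialized per-token vectors (word embedding + two distance codes)."""

    channel: str
    vectors: np.ndarray  # (m, dw + 2 dp)


def channel_indices(instance: CandidateInstance, tree: DepTree) -> dict[str, ChannelIndices]:
    """Build the integer-level content of all three channels."""
    dist = distance_features(instance)
    depth = depth_features(tree, instance)
    out = {}
    linear = np.arange(len(instance.tokens))
    out["linear"] = ChannelIndices(
        "linear", linear,
        np.array([d[0] for d in dist]), np.array([d[1] for d in dist]),
    )
    for name, order in (("dfs", dfs_order(tree)), ("bfs", bfs_order(tree))):
        idx = np.asarray(order)
        out[name] = ChannelIndices(
            name, idx,
            np.array([depth[i][0] for i in order]),
            np.array([depth[i][1] for i in order]),
        )
    return out


def build_channels(
    instance: CandidateInstance,
    tree: DepTree,
    embeddings: np.ndarray,
    vocab: Vocabulary,
    dp: int = 10,
) -> dict[str, ChannelSequence]:
    """Materialize the three channel sequences as float vectors.

    Out-of-vocabulary tokens map to the UNK embedding; this never raises.
    """
    ids = np.array([vocab[t] for t in instance.tokens])
    chans = channel_indices(instance, tree)
    out = {}
    for name, ch in chans.items():
        words = embeddings[ids[ch.order]]
        codes1 = encode_distances(ch.f1, dp)
        codes2 = encode_distances(ch.f2, dp)
        out[name] = ChannelSequence(name, np.concatenate([words, codes1, codes2], axis=1))
    return out
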