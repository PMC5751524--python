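"""Channel features: distances, tree traversals, depth differences, encoding."""

import numpy as np
import pytest

from ddi_dlstm.corpus_io import Parse, Vocabulary
from ddi_dlstm.errors import TreeError
from ddi_dlstm.features import (
    bfs_order,
    build_channels,
    build_tree,
    channel_indices,
    depth_features,
    dfs_order,
    distance_features,
    encode_distance,
    encode_distances,
)
from ddi_dlstm.preprocess import blind_drugs

from conftest import make_parse, random_tree_heads


@pytest.fixture
def fig_instance(fig_sentence, fig_parse):
    fig_sentence.parse = fig_parse
    return blind_drugs(fig_sentence, fig_sentence.pairs[0])


# --------------------------------------------------------------------------
# Oracles (independent of the implementation under test)

def preorder_oracle(heads_0b, root):
    kids = {}
    for j, h in enumerate(heads_0b):
        if h >= 0:
            kids.setdefault(h, []).append(j)

    def walk(u):
        yield u
        for v in sorted(kids.get(u, [])):
            yield from walk(v)

    return list(walk(root))


def levelorder_oracle(heads_0b, root):
    import networkx as nx

    g = nx.Graph((j, h) for j, h in enumerate(heads_0b) if h >= 0)
    g.add_node(root)
    depth = nx.shortest_path_length(g, root)
    order = [root]
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in sorted(k for k, h in enumerate(heads_0b) if h == u):
                nxt.append(v)
        order.extend(nxt)
        frontier = nxt
    return order, depth


class TestDistanceFeatures:
    def test_worked_example(self, fig_instance):
        feats = distance_features(fig_instance)
        assert feats[2] == (5, 12)      # "suggest"
        assert feats[7] == (0, 7)       # the first drug itself
        assert feats[14][1] == 0        # second drug: self-distance

    def test_translation_covariance(self, fig_instance):
        base = distance_features(fig_instance)
        shifted = fig_instance
        k = 3
        shifted.tokens = ["pad"] * k + shifted.tokens
        shifted.drug1_index += k
        shifted.drug2_index += k
        shifted.parse = None
        moved = distance_features(shifted)
        assert moved[k:] == base


class TestTree:
    def test_governor_edge(self, fig_parse):
        tree = build_tree(fig_parse)
        assert tree.head[1] == 2          # "findings" governed by "suggest"
        assert tree.rel[1] == "nsubj"
        assert tree.root_index == 2

    def test_chain_depths(self):
        tree = build_tree(make_parse((2, 3, 0)))
        assert tree.root_index == 2
        np.testing.assert_array_equal(tree.depths(), [2, 1, 0])

    def test_multiple_roots_repaired(self):
        tree = build_tree(make_parse((0, 0, 1)))
        assert tree.root_index == 0
        assert tree.head[1] == 0 and tree.rel[1] == "dep"

    def test_cycle_raises(self):
        with pytest.raises(TreeError):
            build_tree(Parse("c", ("a", "b", "c"), (0, 3, 2), ("root", "dep", "dep")))

    def test_random_tree_depths_match_shortest_path_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(2, 31))
            tree = build_tree(make_parse(random_tree_heads(rng, n)))
            g = nx.Graph((j, h) for j, h in enumerate(tree.head) if h >= 0)
            g.add_node(tree.root_index)
            dist = nx.shortest_path_length(g, tree.root_index)
            np.testing.assert_array_equal(tree.depths(), [dist[i] for i in range(n)])


class TestTraversals:
    def test_single_node(self):
        tree = build_tree(make_parse((0,)))
        assert dfs_order(tree) == [0] == bfs_order(tree)

    def test_small_tree_preorder(self):
        # root 0 with children 1 < 2; 2 has child 3
        tree = build_tree(make_parse((0, 1, 1, 3)))
        assert dfs_order(tree) == [0, 1, 2, 3]
        assert bfs_order(tree) == [0, 1, 2, 3]  # coincide on this shape

    def test_dfs_differs_from_bfs_on_deep_first_subtree(self):
        # root 0: child 1 (which has child 2), and leaf child 3
        tree = build_tree(make_parse((0, 1, 2, 1)))
        assert dfs_order(tree) == [0, 1, 2, 3]
        assert bfs_order(tree) == [0, 1, 3, 2]

    def test_random_trees_match_oracles(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 25))
            heads = random_tree_heads(rng, n)
            tree = build_tree(make_parse(heads))
            heads_0b = [h - 1 for h in heads]
            assert dfs_order(tree) == preorder_oracle(heads_0b, tree.root_index)
            level, depth = levelorder_oracle(heads_0b, tree.root_index)
            assert bfs_order(tree) == level
            # permutation property and traversal-invariant depth multiset
            assert sorted(dfs_order(tree)) == list(range(n))
            assert sorted(bfs_order(tree)) == list(range(n))
            d = tree.depths()
            assert sorted(d[dfs_order(tree)]) == sorted(d[bfs_order(tree)])


class TestDepthFeatures:
    def test_drug_token_is_zero(self, fig_instance, fig_parse):
        tree = build_tree(fig_parse)
        feats = depth_features(tree, fig_instance)
        assert feats[fig_instance.drug1_index][0] == 0
        assert feats[fig_instance.drug2_index][1] == 0

    def test_root_offset_is_minus_drug_depth(self, fig_instance, fig_parse):
        tree = build_tree(fig_parse)
        depths = tree.depths()
        feats = depth_features(tree, fig_instance)
        root = tree.root_index
        assert feats[root] == (-depths[fig_instance.drug1_index],
                               -depths[fig_instance.drug2_index])

    def test_worked_parse_hand_depths(self, fig_instance, fig_parse):
        # depths hand-counted on the fixture tree (root "suggest" = 0)
        hand = [2, 1, 0, 2, 3, 2, 4, 3, 2, 2, 1, 3, 2, 3, 4]
        tree = build_tree(fig_parse)
        np.testing.assert_array_equal(tree.depths(), hand)
        l1, l2 = hand[7], hand[14]
        feats = depth_features(tree, fig_instance)
        assert feats == [(d - l1, d - l2) for d in hand]


class TestEncoding:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _decode(bits):
        sign = -1 if bits[0] else 1
        mag = int("".join(str(int(b)) for b in bits[1:]), 2)
        return sign * mag

    @given(st.integers(min_value=-10_000, max_value=10_000))
    @settings(derandomize=True, max_examples=200)
    def test_roundtrip_up_to_clamp(self, v):
        bits = encode_distance(v)
        decoded = self._decode(bits)
        expect = (-1 if v < 0 else 1) * min(abs(v), 511)
        assert decoded == expect or (v == 0 and decoded == 0)

    def test_zero_is_all_zeros(self):
        assert not encode_distance(0).any()

    def test_five(self):
        np.testing.assert_array_equal(
            encode_distance(5), [0, 0, 0, 0, 0, 0, 0, 1, 0, 1]
        )

    def test_negative_overflow_clamps(self):
        v = encode_distance(-600)
        assert v[0] == 1
        np.testing.assert_array_equal(v[1:], np.ones(9))  # |v| clamped to 511

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(-700, 700, size=(6, 7))
        batch = encode_distances(vals)
        for i in range(6):
            for j in range(7):
                np.testing.assert_array_equal(batch[i, j], encode_distance(vals[i, j]))


class TestBuildChannels:
    def test_layout_and_lengths(self, fig_instance, fig_parse):
        tree = build_tree(fig_parse)
        vocab = Vocabulary(t for t in fig_instance.tokens)
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(len(vocab), 6))
        chans = build_channels(fig_instance, tree, emb, vocab, dp=10)
        m = len(fig_instance.tokens)
        assert set(chans) == {"linear", "dfs", "bfs"}
        idx = channel_indices(fig_instance, tree)
        for name, seq in chans.items():
            assert seq.vectors.shape == (m, 6 + 20)
            ci = idx[name]
            for k in range(m):  # word slice and both code slices, by index arithmetic
                tok = fig_instance.tokens[ci.order[k]]
                np.testing.assert_array_equal(seq.vectors[k, :6], emb[vocab[tok]])
                np.testing.assert_array_equal(seq.vectors[k, 6:16],
                                              encode_distance(int(ci.f1[k])))
                np.testing.assert_array_equal(seq.vectors[k, 16:],
                                              encode_distance(int(ci.f2[k])))

    def test_drug1_position_has_zero_first_code(self, fig_instance, fig_parse):
        tree = build_tree(fig_parse)
        vocab = Vocabulary(fig_instance.tokens)
        emb = np.zeros((len(vocab), 4))
        chans = build_channels(fig_instance, tree, emb, vocab)
        lin = chans["linear"].vectors
        assert not lin[fig_instance.drug1_index, 4:14].any()

    def test_oov_token_maps_to_unk(self, fig_instance, fig_parse):
        tree = build_tree(fig_parse)
        vocab = Vocabulary()  # nothing but specials: every word is OOV
        emb = np.arange(len(vocab) * 2, dtype=float).reshape(len(vocab), 2)
        chans = build_channels(fig_instance, tree, emb, vocab, dp=3)
        lin = chans["linear"].vectors
        non_drug = [i for i, t in enumerate(fig_instance.tokens)
                    if not t.startswith("DRUG_")]
        for i in non_drug:
            np.testing.assert_array_equal(lin[i, :2], emb[vocab["<UNK>"]])
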