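"""Shared fixtures: the two worked-example sentences (the relative-distance
example and the drug-blinding example) with hand-built dependency parses, and
helpers for random trees."""

import numpy as np
import pytest

from ddi_dlstm.corpus_io import AnnotatedSentence, DrugMention, Parse

# Worked example for the distance features: two drug mentions, the word
# "suggest" sits 5 tokens left of the first and 12 left of the second.
FIG_TEXT = ("The findings suggest that the dosage of S-ketamine should be "
            "reduced in patients receiving ticlopidine")

# Hand-built plausible parse over the 15 tokens (only the nsubj(suggest,
# findings) edge is normative; depths are what the tree tests pin down).
FIG_HEADS = (2, 3, 0, 11, 6, 11, 8, 6, 11, 11, 3, 13, 11, 13, 14)  # 1-based
FIG_RELS = ("det", "nsubj", "root", "mark", "det", "nsubjpass", "case",
            "nmod", "aux", "auxpass", "ccomp", "case", "nmod", "acl", "dobj")

# Worked example for drug blinding: three mentions, three candidate pairs.
BLIND_TEXT = ("The CNS-depressant effect of propoxyphene is additive with "
              "that of other CNS depressants, including alcohol")


def mention(sent_text: str, mid: str, surface: str) -> DrugMention:
    start = sent_text.index(surface)
    return DrugMention(id=mid, char_start=start, char_end=start + len(surface) - 1,
                       text=surface, type="drug")


@pytest.fixture
def fig_sentence() -> AnnotatedSentence:
    m1 = mention(FIG_TEXT, "f.e0", "S-ketamine")
    m2 = mention(FIG_TEXT, "f.e1", "ticlopidine")
    sent = AnnotatedSentence(
        id="f", text=FIG_TEXT, mentions=[m1, m2],
        pairs=[("f.p0", "f.e0", "f.e1", "Advice")],
    )
    sent.validate()
    return sent


@pytest.fixture
def fig_parse() -> Parse:
    from ddi_dlstm.corpus_io import tokenize_with_mentions

    sent_mentions = [mention(FIG_TEXT, "f.e0", "S-ketamine"),
                     mention(FIG_TEXT, "f.e1", "ticlopidine")]
    forms, _ = tokenize_with_mentions(FIG_TEXT, sent_mentions)
    return Parse("f", tuple(forms), FIG_HEADS, FIG_RELS)


@pytest.fixture
def blind_sentence() -> AnnotatedSentence:
    ms = [mention(BLIND_TEXT, "b.e0", "propoxyphene"),
          mention(BLIND_TEXT, "b.e1", "CNS depressants"),
          mention(BLIND_TEXT, "b.e2", "alcohol")]
    sent = AnnotatedSentence(
        id="b", text=BLIND_TEXT, mentions=ms,
        pairs=[("b.p0", "b.e0", "b.e1", "Negative"),
               ("b.p1", "b.e0", "b.e2", "Negative"),
               ("b.p2", "b.e1", "b.e2", "Negative")],
    )
    sent.validate()
    return sent


def random_tree_heads(rng: np.random.Generator, n: int) -> tuple[int, ...]:
    """Random rooted tree as 1-based heads: node 1 is the root, every later
    node attaches to an earlier one (acyclic by construction)."""
    heads = [0]
    for i in range(1, n):
        heads.append(int(rng.integers(0, i)) + 1)
    return tuple(heads)


def make_parse(heads: tuple[int, ...], sid: str = "t") -> Parse:
    n = len(heads)
    return Parse(sid, tuple(f"w{i}" for i in range(n)), heads, ("dep",) * n)
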