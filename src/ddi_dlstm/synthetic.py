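"""Desk-scale synthetic corpus generator (XML + CoNLL-U + gold labels).

Each generated sentence holds 2-4 drug mentions and one *labeled* candidate
pair; every other pair in the sentence is Negative.  A positive label is a
deterministic function of a planted trigger token: the trigger word comes
from the class's lexicon and its node is the dependency-tree *parent of both
pair drugs*.  Negative sentences either carry no trigger word, or carry a
distractor — a trigger-lexicon word planted linearly between the drugs but
tree-far from them (depth difference >= +2), so the linear channel alone
cannot separate it from a real trigger while the tree channels can.  A
configurable fraction of negatives instantiate the filtering rules' surface
patterns (same name / apposition / coordination).

Trees are projective by construction: every subtree covers a contiguous token
span.  The class mix defaults to a Negative-heavy distribution with Int
rarest, giving roughly a 1:5.8 positive:negative instance ratio once the
unlabeled pairs are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .corpus_io import (
    AnnotatedSentence,
    DrugMention,
    Parse,
    write_conllu,
    write_ddi_xml,
)
from .errors import ConfigError

DEFAULT_TRIGGERS: dict[str, tuple[str, ...]] = {
    "Advice": ("should", "recommended", "avoid", "caution", "advised"),
    "Effect": ("increases", "decreases", "enhances", "potentiates", "attenuates"),
    "Mechanism": ("metabolism", "clearance", "absorption", "inhibits", "induces"),
    "Int": ("interacts", "interaction", "interfere"),
}

_FILLERS = (
    "the", "a", "of", "in", "with", "patients", "therapy", "treatment", "dose",
    "dosage", "concomitant", "use", "administration", "clinical", "reported",
    "observed", "during", "studies", "may", "be", "when", "given", "oral",
    "daily", "plasma", "levels", "was", "were", "this", "taking",
)

_DRUGS = (
    "alphazol", "betamycin", "gammadine", "deltaprim", "epsilate", "zetatriol",
    "etaprofen", "thetazine", "iotamide", "kappanol", "lambdacin", "mupirex",
    "nuvastat", "xibenol", "omicranil", "pivandrol", "rhotecan", "sigmoxin",
    "taurelin", "upsicaine", "fexarol", "chivex", "psilotan", "omeganib",
    "beta blockers", "loop diuretics", "cns depressants",
)

DEFAULT_CLASS_DISTRIBUTION = {
    "Negative": 0.757,
    "Advice": 0.080,
    "Effect": 0.102,
    "Mechanism": 0.050,
    "Int": 0.011,
}


@dataclass
class GeneratorConfig:
    n_sentences: int = 1000
    class_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTION)
    )
    #: filler counts before / between / after the drug pair
    pre_fillers: tuple[int, int] = (1, 3)
    mid_fillers: tuple[int, int] = (0, 2)
    post_fillers: tuple[int, int] = (1, 3)
    trigger_lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGERS)
    )
    #: fraction of negative-labeled sentences built as Rule-1/2/3 patterns
    filterable_fraction: float = 0.2
    #: fraction of remaining negatives that carry a tree-far distractor trigger
    distractor_fraction: float = 0.3
    #: probabilities of 1 resp. 2 extra (non-pair) drug mentions
    extra_mention_probs: tuple[float, float] = (0.2, 0.05)
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 0:
            raise ConfigError("n_sentences must be >= 0")
        total = sum(self.class_distribution.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigError(f"class distribution sums to {total}, expected 1")
        if not 0 <= self.filterable_fraction <= 1:
            raise ConfigError("filterable_fraction must lie in [0, 1]")
        if self.pre_fillers[0] < 1 or self.post_fillers[0] < 1:
            raise ConfigError(
                "at least one pre and one post filler is required to anchor "
                "the root and keep room for two drug mentions"
            )


@dataclass
class SentenceRecord:
    """In-memory generated sentence before serialization."""

    sid: str
    tokens: list[str]          # collapsed: one entry per mention
    heads: list[int]           # 0-based parent index; -1 = root
    rels: list[str]
    mention_positions: list[int]   # token index of each drug mention
    pair_positions: tuple[int, int]  # labeled pair (token indices)
    label: str
    planted: str               # "trigger" | "distractor" | "rule1|2|3" | "plain"


def _chain(heads, rels, positions, attach_to, direction):
    """Attach a run of positions as a chain ending at ``attach_to``.

    direction +1: each token's head is the next one (left chain into root);
    direction -1: each token's head is the previous one (right chain).
    """
    for k, pos in enumerate(positions):
        nxt = positions[k + 1] if direction == +1 and k + 1 < len(positions) else (
            positions[k - 1] if direction == -1 and k > 0 else attach_to
        )
        heads[pos] = nxt
        rels[pos] = "dep"


def _make_sentence(rng: np.random.Generator, cfg: GeneratorConfig, sid: str) -> SentenceRecord:
    labels = sorted(cfg.class_distribution)
    probs = np.array([cfg.class_distribution[c] for c in labels])
    label = labels[rng.choice(len(labels), p=probs / probs.sum())]

    kind = "trigger" if label != "Negative" else "plain"
    if label == "Negative":
        u = rng.random()
        if u < cfg.filterable_fraction:
            kind = f"rule{rng.integers(1, 4)}"
        elif u < cfg.filterable_fraction + (1 - cfg.filterable_fraction) * cfg.distractor_fraction:
            kind = "distractor"

    filler = lambda: _FILLERS[rng.integers(len(_FILLERS))]
    drug = lambda: _DRUGS[rng.integers(len(_DRUGS))]
    d_a, d_b = drug(), drug()
    while d_b == d_a:
        d_b = drug()

    n_pre = int(rng.integers(cfg.pre_fillers[0], cfg.pre_fillers[1] + 1))
    n_post = int(rng.integers(cfg.post_fillers[0], cfg.post_fillers[1] + 1))

    extras = 0
    if kind in ("trigger", "plain", "distractor"):
        u = rng.random()
        if u < cfg.extra_mention_probs[1]:
            extras = 2
        elif u < cfg.extra_mention_probs[0] + cfg.extra_mention_probs[1]:
            extras = 1
        n_pre = max(n_pre, extras + 1)  # extras replace pre-chain slots

    # --- assemble the token list and structural roles
    tokens: list[str] = []
    pre_pos = list(range(n_pre))
    tokens.extend(filler() for _ in pre_pos)
    extra_positions = []
    if extras:
        slots = rng.choice(n_pre - 1, size=extras, replace=False)  # keep last pre slot a filler
        used = {d_a, d_b}
        for s in sorted(int(x) for x in slots):
            name = drug()
            while name in used:
                name = drug()
            used.add(name)
            tokens[s] = name
            extra_positions.append(s)

    block_start = len(tokens)
    pos_a = block_start
    tokens.append(d_a)

    mid_tokens: list[str] = []
    trigger_pos = distractor_pos = None
    if kind == "trigger":
        n_mid1 = int(rng.integers(cfg.mid_fillers[0], cfg.mid_fillers[1] + 1))
        n_mid2 = int(rng.integers(cfg.mid_fillers[0], cfg.mid_fillers[1] + 1))
        lex = cfg.trigger_lexicons[label]
        trig = lex[rng.integers(len(lex))]
        mid_tokens = [filler() for _ in range(n_mid1)] + [trig] + [filler() for _ in range(n_mid2)]
        trigger_pos = pos_a + 1 + n_mid1
    elif kind == "distractor":
        all_trigs = [w for lex in cfg.trigger_lexicons.values() for w in lex]
        trig = all_trigs[rng.integers(len(all_trigs))]
        n_mid2 = int(rng.integers(cfg.mid_fillers[0], cfg.mid_fillers[1] + 1))
        mid_tokens = [filler(), trig] + [filler() for _ in range(n_mid2)]
        distractor_pos = pos_a + 2
    elif kind == "plain":
        n_mid = int(rng.integers(max(1, cfg.mid_fillers[0]), cfg.mid_fillers[1] + 2))
        mid_tokens = [filler() for _ in range(n_mid)]
    elif kind == "rule1":
        d_b = d_a
        mid_tokens = [filler() for _ in range(int(rng.integers(1, 3)))]
    elif kind == "rule2":
        mid_tokens = ["such", "as"] if rng.random() < 0.5 else ["("]
    elif kind == "rule3":
        mid_tokens = [[","], ["and"], ["or"], [",", "and"]][rng.integers(4)]

    tokens.extend(mid_tokens)
    pos_b = len(tokens)
    tokens.append(d_b)
    if kind == "rule2" and mid_tokens == ["("]:
        tokens.append(")")
    post_start = len(tokens)
    tokens.extend(filler() for _ in range(n_post))
    root = post_start  # first post filler anchors the tree

    # --- heads (projective by construction)
    n = len(tokens)
    heads = [-2] * n
    rels = ["dep"] * n
    heads[root] = -1
    rels[root] = "root"
    _chain(heads, rels, list(range(post_start + 1, n)), root, direction=-1)
    _chain(heads, rels, pre_pos, root, direction=+1)

    if kind == "trigger":
        heads[trigger_pos] = root
        rels[trigger_pos] = "advmod"
        heads[pos_a] = trigger_pos
        heads[pos_b] = trigger_pos
        rels[pos_a], rels[pos_b] = "nsubj", "obj"
        for p in range(pos_a + 1, trigger_pos):
            heads[p] = pos_a
        for p in range(trigger_pos + 1, pos_b):
            heads[p] = pos_b
    elif kind == "distractor":
        heads[pos_a] = root
        heads[pos_b] = root
        rels[pos_a], rels[pos_b] = "nsubj", "obj"
        heads[pos_a + 1] = pos_a           # filler under DRUG_a
        heads[distractor_pos] = pos_a + 1  # trigger word two edges below
        for p in range(distractor_pos + 1, pos_b):
            heads[p] = pos_b
    elif kind in ("plain", "rule1"):
        heads[pos_a] = root
        heads[pos_b] = root
        rels[pos_a], rels[pos_b] = "nsubj", "obj"
        for p in range(pos_a + 1, pos_b):
            heads[p] = pos_a
    else:  # rule2 / rule3: second drug hangs off the first
        heads[pos_a] = root
        rels[pos_a] = "nsubj"
        heads[pos_b] = pos_a
        rels[pos_b] = "appos" if kind == "rule2" else "conj"
        for p in range(pos_a + 1, pos_b):
            heads[p] = pos_b
        if tokens[pos_b + 1 : pos_b + 2] == [")"]:
            heads[pos_b + 1] = pos_b

    mention_positions = sorted(extra_positions + [pos_a, pos_b])
    return SentenceRecord(
        sid=sid,
        tokens=tokens,
        heads=heads,
        rels=rels,
        mention_positions=mention_positions,
        pair_positions=(pos_a, pos_b),
        label=label,
        planted=kind,
    )


def record_to_objects(rec: SentenceRecord) -> tuple[AnnotatedSentence, Parse]:
    """Serialize a record into an annotated sentence plus its parse."""
    text_parts: list[str] = []
    spans: dict[int, tuple[int, int]] = {}
    cursor = 0
    for i, tok in enumerate(rec.tokens):
        if i > 0:
            cursor += 1  # single space
        spans[i] = (cursor, cursor + len(tok) - 1)
        text_parts.append(tok)
        cursor += len(tok)
    text = " ".join(text_parts)

    mentions = []
    pos_to_id = {}
    for k, pos in enumerate(rec.mention_positions):
        mid = f"{rec.sid}.e{k}"
        pos_to_id[pos] = mid
        s, e = spans[pos]
        mentions.append(DrugMention(id=mid, char_start=s, char_end=e,
                                    text=rec.tokens[pos], type="drug"))
    pairs = []
    labeled = tuple(sorted(rec.pair_positions))
    for k, (p1, p2) in enumerate(combinations(rec.mention_positions, 2)):
        label = rec.label if (p1, p2) == labeled else "Negative"
        pairs.append((f"{rec.sid}.p{k}", pos_to_id[p1], pos_to_id[p2], label))

    sent = AnnotatedSentence(id=rec.sid, text=text, mentions=mentions, pairs=pairs)
    sent.validate()
    parse = Parse(rec.sid, tuple(rec.tokens), tuple(h + 1 for h in rec.heads),
                  tuple(rec.rels))
    return sent, parse


def generate_records(cfg: GeneratorConfig) -> list[SentenceRecord]:
    rng = np.random.default_rng(cfg.seed)
    return [_make_sentence(rng, cfg, f"s{i}") for i in range(cfg.n_sentences)]


def generate(cfg: GeneratorConfig, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write corpus.xml, parses.conllu and gold.tsv; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_records(cfg)
    sentences, parses = [], []
    for rec in records:
        sent, parse = record_to_objects(rec)
        sentences.append(sent)
        parses.append(parse)
    xml_path = out_dir / "corpus.xml"
    conllu_path = out_dir / "parses.conllu"
    gold_path = out_dir / "gold.tsv"
    write_ddi_xml(sentences, xml_path)
    write_conllu(parses, conllu_path)
    with open(gold_path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for pid, _, _, label in sent.pairs:
                fh.write(f"{pid}\t{label}\n")
    return xml_path, conllu_path, gold_path


def oracle_label(
    rec: SentenceRecord,
    lexicons: dict[str, tuple[str, ...]] | None = None,
) -> str:
    """Recompute the labeled pair's class from the planted structure alone:
    a trigger-lexicon word whose node is the parent of both pair drugs gives
    its class; anything else is Negative."""
    lexicons = lexicons or DEFAULT_TRIGGERS
    p1, p2 = rec.pair_positions
    h1, h2 = rec.heads[p1], rec.heads[p2]
    if h1 == h2 and h1 >= 0:
        word = rec.tokens[h1]
        for cls, lex in lexicons.items():
            if word in lex:
                return cls
    return "Negative"
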