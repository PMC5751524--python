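"""Corpus readers and writers: DDI-style XML, CoNLL-U parses, word2vec vectors.

The sentence corpus arrives as XML (one ``document`` holding ``sentence``
elements with ``entity`` and ``pair`` children, char offsets given as
``start-end`` with an inclusive end).  Dependency parses arrive separately as
CoNLL-U keyed by ``sent_id``; the parser is external and its output is
consumed over *collapsed* tokens, i.e. each drug mention is one parse token
regardless of how many words it spans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

from .errors import (
    AlignmentError,
    ConfigError,
    CorpusParseError,
    CorpusValidationError,
)

#: The five relation classes, in fixed order (used for argmax tie-breaking).
CLASSES = ("Advice", "Effect", "Mechanism", "Int", "Negative")
POSITIVE_CLASSES = CLASSES[:4]

#: Placeholder tokens introduced by drug blinding.  They stay uppercase while
#: every other token is lowercased, so they are distinct vocabulary items.
DRUG_1, DRUG_2, DRUG_N = "DRUG_1", "DRUG_2", "DRUG_N"
PAD, UNK = "<PAD>", "<UNK>"
SPECIALS = (PAD, UNK, DRUG_1, DRUG_2, DRUG_N)

_LABEL_ALIASES = {
    "advice": "Advice",
    "advise": "Advice",  # the 2013 corpus spells the class "advise"
    "effect": "Effect",
    "mechanism": "Mechanism",
    "int": "Int",
    "negative": "Negative",
    "false": "Negative",
}


def normalize_label(raw: str) -> str:
    try:
        return _LABEL_ALIASES[raw.strip().lower()]
    except KeyError:
        raise CorpusValidationError(f"unknown interaction label {raw!r}") from None


@dataclass(frozen=True)
class DrugMention:
    """A drug entity span; offsets are 0-based with inclusive end."""

    id: str
    char_start: int
    char_end: int
    text: str
    type: str = "drug"

    def __post_init__(self):
        if self.char_start > self.char_end:
            raise CorpusValidationError(
                f"mention {self.id}: char_start {self.char_start} > char_end {self.char_end}"
            )


@dataclass(frozen=True)
class Parse:
    """One dependency parse: forms, 1-based heads (0 = root), relation labels."""

    sent_id: str
    forms: tuple[str, ...]
    heads: tuple[int, ...]   # 1-based; 0 marks the root
    rels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.forms)


@dataclass
class AnnotatedSentence:
    id: str
    text: str
    mentions: list[DrugMention] = field(default_factory=list)
    #: (pair_id, mention_id_1, mention_id_2, label)
    pairs: list[tuple[str, str, str, str]] = field(default_factory=list)
    parse: Parse | None = None

    def mention_by_id(self, mid: str) -> DrugMention:
        for m in self.mentions:
            if m.id == mid:
                return m
        raise CorpusValidationError(f"sentence {self.id}: unknown mention id {mid!r}")

    def validate(self) -> None:
        ids = [m.id for m in self.mentions]
        if len(set(ids)) != len(ids):
            raise CorpusValidationError(f"sentence {self.id}: duplicate mention ids")
        for m in self.mentions:
            sub = self.text[m.char_start : m.char_end + 1]
            if sub != m.text:
                raise CorpusValidationError(
                    f"sentence {self.id}: mention {m.id} text {m.text!r} does not "
                    f"match sentence span {sub!r}"
                )
        for pid, e1, e2, label in self.pairs:
            if e1 == e2:
                raise CorpusValidationError(f"sentence {self.id}: pair {pid} repeats {e1}")
            for e in (e1, e2):
                if e not in ids:
                    raise CorpusValidationError(
                        f"sentence {self.id}: pair {pid} references unknown entity {e!r}"
                    )
            normalize_label(label)


# ---------------------------------------------------------------------------
# Tokenization

_TOKEN_RE = re.compile(r"\w+(?:[-/'’]\w+)*|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace-and-punctuation tokenization.

    Hyphenated and slashed compounds stay single tokens ("S-ketamine"),
    punctuation becomes its own token.  Deterministic; "" -> [].
    """
    return _TOKEN_RE.findall(text)


def tokenize_with_mentions(
    text: str, mentions: Sequence[DrugMention]
) -> tuple[list[str], dict[str, int]]:
    """Tokenize a sentence, collapsing every mention span to one token.

    Returns the token list (mention tokens keep their raw surface text) and a
    map mention id -> token index.  Mentions must be non-overlapping; an
    overlap raises :class:`CorpusValidationError`.
    """
    order = sorted(mentions, key=lambda m: m.char_start)
    for a, b in zip(order, order[1:]):
        if b.char_start <= a.char_end:
            raise CorpusValidationError(
                f"overlapping mentions {a.id} and {b.id}"
            )
    tokens: list[str] = []
    index: dict[str, int] = {}
    cursor = 0
    for m in order:
        tokens.extend(tokenize(text[cursor : m.char_start]))
        index[m.id] = len(tokens)
        tokens.append(m.text)
        cursor = m.char_end + 1
    tokens.extend(tokenize(text[cursor:]))
    return tokens, index


# ---------------------------------------------------------------------------
# DDI XML dialect

def read_ddi_xml(path: str | Path) -> list[AnnotatedSentence]:
    """Read a corpus file in the DDI XML dialect.

    Labels are mapped to the canonical five classes: ``ddi="false"`` becomes
    Negative, ``ddi="true"`` takes its (case-normalized) ``type`` attribute.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"{path}: malformed XML: {exc}") from exc
    sentences: list[AnnotatedSentence] = []
    for sent_el in tree.iter("sentence"):
        sid = sent_el.get("id", "")
        text = sent_el.get("text", "")
        sent = AnnotatedSentence(id=sid, text=text)
        for ent in sent_el.iter("entity"):
            offs = ent.get("charOffset", "")
            if ";" in offs:
                raise CorpusParseError(
                    f"sentence {sid}: discontinuous charOffset {offs!r} unsupported"
                )
            try:
                start_s, end_s = offs.split("-")
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise CorpusParseError(
                    f"sentence {sid}: bad charOffset {offs!r} on entity {ent.get('id')}"
                ) from None
            sent.mentions.append(
                DrugMention(
                    id=ent.get("id", ""),
                    char_start=start,
                    char_end=end,
                    text=ent.get("text", ""),
                    type=ent.get("type", "drug"),
                )
            )
        for pair in sent_el.iter("pair"):
            ddi = pair.get("ddi", "false").lower()
            label = "Negative" if ddi == "false" else normalize_label(pair.get("type", ""))
            sent.pairs.append((pair.get("id", ""), pair.get("e1", ""), pair.get("e2", ""), label))
        sent.validate()
        sentences.append(sent)
    return sentences


def write_ddi_xml(sentences: Iterable[AnnotatedSentence], path: str | Path,
                  document_id: str = "d0") -> None:
    root = etree.Element("document", id=document_id)
    for sent in sentences:
        sent_el = etree.SubElement(root, "sentence", id=sent.id, text=sent.text)
        for m in sent.mentions:
            etree.SubElement(
                sent_el,
                "entity",
                id=m.id,
                charOffset=f"{m.char_start}-{m.char_end}",
                type=m.type,
                text=m.text,
            )
        for pid, e1, e2, label in sent.pairs:
            attrs = {"id": pid, "e1": e1, "e2": e2}
            if label == "Negative":
                attrs["ddi"] = "false"
            else:
                attrs["ddi"] = "true"
                attrs["type"] = label.lower()
            etree.SubElement(sent_el, "pair", **attrs)
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# CoNLL-U

def read_conllu(path: str | Path) -> dict[str, Parse]:
    """Read CoNLL-U parses keyed by their ``sent_id`` metadata.

    Only ID, FORM, HEAD and DEPREL columns are used; multiword-token and
    empty-node lines (ids containing '-' or '.') are skipped.
    """
    path = Path(path)
    parses: dict[str, Parse] = {}
    sent_id = None
    forms: list[str] = []
    heads: list[int] = []
    rels: list[str] = []

    def flush():
        nonlocal sent_id, forms, heads, rels
        if forms:
            if sent_id is None:
                raise CorpusParseError(f"{path}: sentence block without sent_id")
            parses[sent_id] = Parse(sent_id, tuple(forms), tuple(heads), tuple(rels))
        sent_id, forms, heads, rels = None, [], [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*sent_id\s*=\s*(\S+)", line)
                if m:
                    sent_id = m.group(1)
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise CorpusParseError(f"{path}:{lineno}: expected >=8 columns")
            if "-" in cols[0] or "." in cols[0]:
                continue
            forms.append(cols[1])
            try:
                heads.append(int(cols[6]))
            except ValueError:
                raise CorpusParseError(f"{path}:{lineno}: non-integer HEAD {cols[6]!r}") from None
            rels.append(cols[7])
    flush()
    return parses


def write_conllu(parses: Iterable[Parse], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in parses:
            fh.write(f"# sent_id = {p.sent_id}\n")
            for i, (form, head, rel) in enumerate(zip(p.forms, p.heads, p.rels), 1):
                fh.write(f"{i}\t{form}\t_\t_\t_\t_\t{head}\t{rel}\t_\t_\n")
            fh.write("\n")


def attach_parses(
    sentences: Iterable[AnnotatedSentence], parses: dict[str, Parse]
) -> list[AnnotatedSentence]:
    """Attach parses to sentences by id, checking token alignment.

    The parse must have exactly one token per collapsed sentence token
    (mentions count as one token each); a mismatch raises
    :class:`AlignmentError` rather than truncating silently.
    """
    out = []
    for sent in sentences:
        parse = parses.get(sent.id)
        if parse is not None:
            tokens, _ = tokenize_with_mentions(sent.text, sent.mentions)
            if len(parse) != len(tokens):
                raise AlignmentError(
                    f"sentence {sent.id}: parse has {len(parse)} tokens, "
                    f"tokenized sentence has {len(tokens)}"
                )
        sent.parse = parse
        out.append(sent)
    return out


# ---------------------------------------------------------------------------
# Vocabulary and embeddings

class Vocabulary:
    """Dense token -> id map with PAD/UNK and drug-placeholder specials."""

    def __init__(self, tokens: Iterable[str] = ()):
        self._id: dict[str, int] = {}
        for t in SPECIALS:
            self._id[t] = len(self._id)
        for t in tokens:
            self.add(t)

    def add(self, token: str) -> int:
        if token not in self._id:
            self._id[token] = len(self._id)
        return self._id[token]

    def __len__(self) -> int:
        return len(self._id)

    def __contains__(self, token: str) -> bool:
        return token in self._id

    def __getitem__(self, token: str) -> int:
        return self._id.get(token, self._id[UNK])

    @property
    def pad_id(self) -> int:
        return self._id[PAD]

    def tokens(self) -> list[str]:
        return sorted(self._id, key=self._id.get)

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha1("\n".join(self.tokens()).encode()).hexdigest()


def load_word_vectors(
    path: str | Path,
    vocab: Vocabulary,
    dw: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Build the embedding matrix from a word2vec text-format file.

    Known words take the file's vectors verbatim; unknown words (and the
    specials) are drawn uniformly from [-1, 1].  Returns (matrix, number of
    unknown content words — the PAD/UNK/placeholder specials are not
    counted).  A file dimension different from ``dw`` is a config error.
    """
    matrix = rng.uniform(-1.0, 1.0, size=(len(vocab), dw))
    known: set[int] = set()
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().split()
        header = len(first) == 2 and all(s.lstrip("-").isdigit() for s in first)
        if not header and first:
            _consume_vector_line(first, vocab, matrix, known, dw, path)
        for line in fh:
            parts = line.split()
            if parts:
                _consume_vector_line(parts, vocab, matrix, known, dw, path)
    unknown = (len(vocab) - len(SPECIALS)) - len(known)
    return matrix, unknown


def _consume_vector_line(parts, vocab, matrix, known, dw, path):
    word, values = parts[0], parts[1:]
    if len(values) != dw:
        raise ConfigError(
            f"{path}: vector for {word!r} has dimension {len(values)}, expected {dw}"
        )
    if word in vocab:
        idx = vocab[word]
        matrix[idx] = np.asarray(values, dtype=float)
        known.add(idx)


def random_embeddings(vocab: Vocabulary, dw: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform [-1, 1] initialization for every word (the no-pretraining mode)."""
    return rng.uniform(-1.0, 1.0, size=(len(vocab), dw))
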