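"""Candidate generation: drug blinding and rule-based negative filtering.

Every annotated drug pair becomes one candidate instance.  The pair's
mentions are replaced (in sentence order) by DRUG_1 and DRUG_2, every other
drug in the sentence by DRUG_N, each mention collapsing to a single token;
all remaining tokens are lowercased.  Three surface rules then remove
candidates that are almost surely non-interacting:

* Rule 1 — the two mentions share the same name (case-insensitive exact
  string match after whitespace normalization);
* Rule 2 — apposition/exemplification: ``DRUG_1 ( DRUG_N* DRUG_2`` or
  ``DRUG_1 such as DRUG_N* DRUG_2`` (optional commas between drugs);
* Rule 3 — coordination: everything between DRUG_1 and DRUG_2 is drawn from
  {",", "and", "or", DRUG_N} and the gap is non-empty, i.e. the two drugs sit
  in one coordinate list ("X, Y, and Z" removes (X, Y) as well as (X, Z)).

Filtering never reads the label; the report tallies removals per rule and per
class so wrongly removed positives are visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import (
    CLASSES,
    DRUG_1,
    DRUG_2,
    DRUG_N,
    AnnotatedSentence,
    Parse,
    tokenize_with_mentions,
)
from .errors import ContractError


@dataclass
class CandidateInstance:
    """One blinded drug-pair sentence with its label and aligned parse."""

    sentence_id: str
    pair_id: str
    tokens: list[str]
    drug1_index: int
    drug2_index: int
    label: str
    #: original (unblinded) mention surface texts, used by filter Rule 1
    mention_texts: tuple[str, str] = ("", "")
    parse: Parse | None = None
    filtered: bool = False
    filter_rule: int | None = None
    valid: bool = True

    def __post_init__(self):
        if self.valid:
            if self.tokens.count(DRUG_1) != 1 or self.tokens.count(DRUG_2) != 1:
                raise ContractError(
                    f"{self.sentence_id}/{self.pair_id}: blinding must yield exactly "
                    "one DRUG_1 and one DRUG_2"
                )
            if not self.drug1_index < self.drug2_index:
                raise ContractError(
                    f"{self.sentence_id}/{self.pair_id}: DRUG_1 must precede DRUG_2"
                )
            if self.parse is not None and len(self.parse) != len(self.tokens):
                raise ContractError(
                    f"{self.sentence_id}/{self.pair_id}: parse/token length mismatch"
                )

    def to_json(self) -> str:
        d = asdict(self)
        if self.parse is not None:
            d["parse"] = {
                "sent_id": self.parse.sent_id,
                "forms": list(self.parse.forms),
                "heads": list(self.parse.heads),
                "rels": list(self.parse.rels),
            }
        return json.dumps(d)

    @classmethod
    def from_json(cls, line: str) -> "CandidateInstance":
        d = json.loads(line)
        if d.get("parse"):
            p = d["parse"]
            d["parse"] = Parse(p["sent_id"], tuple(p["forms"]), tuple(p["heads"]),
                               tuple(p["rels"]))
        d["mention_texts"] = tuple(d.get("mention_texts", ("", "")))
        return cls(**d)


def blind_drugs(sentence: AnnotatedSentence, pair: tuple[str, str, str, str]) -> CandidateInstance:
    """Blind one candidate pair.

    DRUG_1 is the pair mention with the smaller char offset (sentence order);
    all other mentions become DRUG_N.  Overlapping mention spans make the
    instance invalid rather than raising.
    """
    pair_id, e1, e2, label = pair
    m1 = sentence.mention_by_id(e1)
    m2 = sentence.mention_by_id(e2)
    if m1.char_start > m2.char_start:
        m1, m2 = m2, m1
    try:
        raw_tokens, index = tokenize_with_mentions(sentence.text, sentence.mentions)
    except Exception:
        return CandidateInstance(sentence.id, pair_id, [], 0, 0, label,
                                 (m1.text, m2.text), valid=False)
    tokens = []
    for i, tok in enumerate(raw_tokens):
        if i == index[m1.id]:
            tokens.append(DRUG_1)
        elif i == index[m2.id]:
            tokens.append(DRUG_2)
        elif i in {index[m.id] for m in sentence.mentions}:
            tokens.append(DRUG_N)
        else:
            tokens.append(tok.lower())
    return CandidateInstance(
        sentence_id=sentence.id,
        pair_id=pair_id,
        tokens=tokens,
        drug1_index=index[m1.id],
        drug2_index=index[m2.id],
        label=label,
        mention_texts=(m1.text, m2.text),
        parse=sentence.parse,
    )


def candidate_instances(sentences: Iterable[AnnotatedSentence]) -> list[CandidateInstance]:
    """One blinded instance per annotated pair, in corpus order."""
    out = []
    for sent in sentences:
        for pair in sent.pairs:
            out.append(blind_drugs(sent, pair))
    return out


# ---------------------------------------------------------------------------
# Negative instance filtering

@dataclass
class FilterReport:
    """Removal bookkeeping: per rule, per class, and totals."""

    total_before: int = 0
    removed_by_rule: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    removed_by_class: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})
    class_before: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})

    @property
    def total_removed(self) -> int:
        return sum(self.removed_by_rule.values())

    @property
    def total_after(self) -> int:
        return self.total_before - self.total_removed

    def class_after(self, label: str) -> int:
        return self.class_before[label] - self.removed_by_class[label]

    def removed_fraction(self, label: str | None = None) -> float:
        """Fraction of (optionally per-class) instances removed."""
        if label is None:
            return self.total_removed / self.total_before if self.total_before else 0.0
        before = self.class_before[label]
        return self.removed_by_class[label] / before if before else 0.0

    def to_json(self) -> str:
        return json.dumps({
            "total_before": self.total_before,
            "total_after": self.total_after,
            "removed_by_rule": self.removed_by_rule,
            "removed_by_class": self.removed_by_class,
            "class_before": self.class_before,
        })


def negative_positive_ratio(class_counts: dict[str, int]) -> float:
    """Negative:positive instance ratio of a count table (e.g. corpus statistics)."""
    pos = sum(v for k, v in class_counts.items() if k != "Negative")
    if pos == 0:
        raise ContractError("no positive instances in count table")
    return class_counts["Negative"] / pos


_COORD_TOKENS = {",", "and", "or", DRUG_N}


def _match_rule(inst: CandidateInstance) -> int | None:
    """First matching rule (1 -> 2 -> 3) or None.  Never reads the label."""
    t1 = " ".join(inst.mention_texts[0].split()).lower()
    t2 = " ".join(inst.mention_texts[1].split()).lower()
    if t1 and t1 == t2:
        return 1
    toks = inst.tokens
    gap = toks[inst.drug1_index + 1 : inst.drug2_index]

    def drugs_only(seq: Sequence[str]) -> bool:
        return all(t in (DRUG_N, ",") for t in seq)

    # Rule 2: DRUG_1 ( DRUG_N* DRUG_2   /   DRUG_1 such as DRUG_N* DRUG_2
    if len(gap) >= 1 and gap[0] == "(" and drugs_only(gap[1:]):
        return 2
    if len(gap) >= 2 and gap[0] == "such" and gap[1] == "as" and drugs_only(gap[2:]):
        return 2
    # Rule 3: coordinate structure — gap made only of commas/conjunctions/DRUG_N
    if gap and all(t in _COORD_TOKENS for t in gap):
        return 3
    return None


def filter_negatives(
    instances: Iterable[CandidateInstance],
) -> tuple[list[CandidateInstance], FilterReport]:
    """Remove likely-negative candidates; returns (retained, report).

    Removed instances are marked ``filtered`` with their matching rule so the
    caller can keep them in an evaluation universe.  Idempotent on the
    retained set.
    """
    report = FilterReport()
    retained = []
    for inst in instances:
        report.total_before += 1
        report.class_before[inst.label] += 1
        rule = _match_rule(inst) if inst.valid else None
        if rule is None:
            retained.append(inst)
        else:
            inst.filtered = True
            inst.filter_rule = rule
            report.removed_by_rule[rule] += 1
            report.removed_by_class[inst.label] += 1
    return retained, report


# ---------------------------------------------------------------------------
# Instance file IO (JSON lines)

def write_instances(instances: Iterable[CandidateInstance], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(inst.to_json() + "\n")


def read_instances(path: str | Path) -> list[CandidateInstance]:
    with open(path, encoding="utf-8") as fh:
        return [CandidateInstance.from_json(line) for line in fh if line.strip()]
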