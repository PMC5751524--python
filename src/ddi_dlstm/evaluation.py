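"""Challenge-style scoring for 5-way interaction classification.

The Negative class is not scored: precision/recall/F are reported per
positive class (Advice, Effect, Mechanism, Int), the overall micro scores
pool TP/FP/FN over those four classes, and MAVG is the arithmetic mean of
the four class F-scores.  The confusion matrix is 5x5 with gold labels on
rows; row normalization makes each row sum to 1.  Instances removed by
test-set filtering enter the evaluation universe as predicted-Negative, so a
wrongly filtered positive costs recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import CLASSES, POSITIVE_CLASSES
from .errors import ContractError

_IDX = {c: i for i, c in enumerate(CLASSES)}


def f_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def macro_average(f_scores: Sequence[float]) -> float:
    """Arithmetic mean of class F-scores (MAVG)."""
    return float(np.mean(f_scores))


@dataclass
class ClassScore:
    precision: float
    recall: float
    f: float
    support: int


@dataclass
class EvalReport:
    per_class: dict[str, ClassScore]
    micro_p: float
    micro_r: float
    micro_f: float
    mavg: float
    confusion_counts: np.ndarray
    confusion_normalized: np.ndarray
    length_bins: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"precision": s.precision, "recall": s.recall, "f": s.f,
                    "support": s.support}
                for c, s in self.per_class.items()
            },
            "micro": {"precision": self.micro_p, "recall": self.micro_r,
                      "f": self.micro_f},
            "mavg": self.mavg,
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "length_bins": self.length_bins,
            "classes": list(CLASSES),
        }


def confusion(gold: Sequence[str], pred: Sequence[str]) -> np.ndarray:
    """5x5 count matrix; rows = gold (targeted) label, columns = predicted."""
    if len(gold) != len(pred):
        raise ContractError("gold and pred must have equal length")
    mat = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for g, p in zip(gold, pred):
        mat[_IDX[g], _IDX[p]] += 1
    return mat


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, mat / sums, 0.0)
    return out


def score(gold: Sequence[str], pred: Sequence[str]) -> EvalReport:
    """Class-wise and pooled (micro) precision/recall/F over positive classes."""
    mat = confusion(gold, pred)
    per_class: dict[str, ClassScore] = {}
    tp_total = fp_total = fn_total = 0
    for c in POSITIVE_CLASSES:
        i = _IDX[c]
        tp = int(mat[i, i])
        fp = int(mat[:, i].sum() - tp)
        fn = int(mat[i, :].sum() - tp)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        per_class[c] = ClassScore(p, r, f_score(p, r), support=int(mat[i, :].sum()))
        tp_total += tp
        fp_total += fp
        fn_total += fn
    micro_p = tp_total / (tp_total + fp_total) if tp_total + fp_total else 0.0
    micro_r = tp_total / (tp_total + fn_total) if tp_total + fn_total else 0.0
    return EvalReport(
        per_class=per_class,
        micro_p=micro_p,
        micro_r=micro_r,
        micro_f=f_score(micro_p, micro_r),
        mavg=macro_average([s.f for s in per_class.values()]),
        confusion_counts=mat,
        confusion_normalized=_normalize_rows(mat),
    )


def length_binned_f(
    gold: Sequence[str], pred: Sequence[str], lengths: Sequence[int],
    bin_width: int = 10,
) -> list[dict]:
    """Micro F per token-length bin ([1-10], [11-20], ...).

    Empty bins are omitted; a bin whose micro F is undefined because it holds
    no positive instance and no positive prediction reports ``None``.
    """
    if not (len(gold) == len(pred) == len(lengths)):
        raise ContractError("gold, pred and lengths must align")
    bins: dict[int, list[int]] = {}
    for i, ln in enumerate(lengths):
        if ln < 1:
            raise ContractError(f"instance {i}: non-positive length {ln}")
        bins.setdefault((ln - 1) // bin_width, []).append(i)
    table = []
    for b in sorted(bins):
        idx = bins[b]
        g = [gold[i] for i in idx]
        p = [pred[i] for i in idx]
        rep = score(g, p)
        has_positive = any(x != "Negative" for x in g) or any(x != "Negative" for x in p)
        table.append({
            "bin": f"{b * bin_width + 1}-{(b + 1) * bin_width}",
            "count": len(idx),
            "f": rep.micro_f if has_positive else None,
        })
    return table


def assemble_universe(
    retained_gold: Sequence[str],
    retained_pred: Sequence[str],
    filtered_gold: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Append test-filtered instances as predicted-Negative to the universe."""
    gold = list(retained_gold) + list(filtered_gold)
    pred = list(retained_pred) + ["Negative"] * len(filtered_gold)
    return gold, pred
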