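"""End-to-end pipeline glue: files -> instances -> trained model -> report.

Also hosts the desk-scale synthetic learnability experiment used by the test
suite: train on a generated corpus with a planted, tree-mediated class signal
and score a held-out generated test set with the challenge protocol
(test-filtered instances stay in the universe as predicted-Negative).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluation
from .config import HyperParams
from .corpus_io import attach_parses, read_conllu, read_ddi_xml
from .evaluation import EvalReport, assemble_universe
from .model import RelationClassifier
from .preprocess import (
    CandidateInstance,
    FilterReport,
    candidate_instances,
    filter_negatives,
)
from .synthetic import GeneratorConfig, generate
from .training import TrainHistory, build_vocabulary, featurize, train

#: Desk-scale hyperparameters for the synthetic experiment.  Small hidden
#: width and few epochs keep a full 3-seed run in CPU-minutes; the sampling
#: parameters keep their standard values.
DESK_HP = dict(dw=24, dp=10, num=24, batch_size=64, max_epochs=8,
               dev_fraction=0.1, patience=8, la=0.01, l2=1e-4)


def load_corpus(xml_path, conllu_path) -> list:
    """Read sentences and parses and align them by sentence id."""
    sentences = read_ddi_xml(xml_path)
    parses = read_conllu(conllu_path)
    return attach_parses(sentences, parses)


def preprocess_corpus(
    xml_path, conllu_path, apply_filter: bool = True
) -> tuple[list[CandidateInstance], list[CandidateInstance], FilterReport]:
    """Blind and (optionally) filter; returns (retained, removed, report)."""
    sentences = load_corpus(xml_path, conllu_path)
    instances = candidate_instances(sentences)
    if not apply_filter:
        return instances, [], FilterReport(total_before=len(instances))
    retained, report = filter_negatives(instances)
    removed = [i for i in instances if i.filtered]
    return retained, removed, report


@dataclass
class ExperimentResult:
    report: EvalReport
    history: TrainHistory
    model: RelationClassifier
    n_train: int
    n_test: int


def run_experiment(
    train_instances: list[CandidateInstance],
    test_retained: list[CandidateInstance],
    test_removed: list[CandidateInstance],
    hp: HyperParams,
    embeddings: np.ndarray | None = None,
) -> ExperimentResult:
    """Train on preprocessed instances and score the full test universe."""
    vocab = build_vocabulary(train_instances)
    rng = np.random.default_rng(hp.seed)
    model = RelationClassifier(vocab, hp, rng, embeddings)
    history = train(train_instances, model, hp)
    test_feats = featurize(test_retained, vocab)
    pred = model.predict_labels(test_feats)
    gold, pred = assemble_universe(
        [i.label for i in test_retained], pred, [i.label for i in test_removed]
    )
    lengths = [len(i.tokens) for i in test_retained] + [len(i.tokens) for i in test_removed]
    report = evaluation.score(gold, pred)
    report.length_bins = evaluation.length_binned_f(gold, pred, lengths)
    return ExperimentResult(report, history, model,
                            n_train=len(train_instances), n_test=len(gold))


def synthetic_experiment(
    seed: int,
    n_train: int = 2000,
    n_test: int = 600,
    channels: tuple[str, ...] = ("linear", "dfs", "bfs"),
    **hp_overrides,
) -> ExperimentResult:
    """Generate train/test corpora, run the whole pipeline, score held-out F.

    ``seed`` drives corpus generation, initialization, sampling and dropout.
    ``channels`` allows channel-ablation runs (e.g. linear only).
    """
    train_cfg = GeneratorConfig(n_sentences=n_train, seed=seed)
    test_cfg = GeneratorConfig(n_sentences=n_test, seed=seed + 500_000)
    with tempfile.TemporaryDirectory() as tmp:
        tr_dir, te_dir = Path(tmp) / "train", Path(tmp) / "test"
        xml_tr, conllu_tr, _ = generate(train_cfg, tr_dir)
        xml_te, conllu_te, _ = generate(test_cfg, te_dir)
        train_retained, _, _ = preprocess_corpus(xml_tr, conllu_tr)
        test_retained, test_removed, _ = preprocess_corpus(xml_te, conllu_te)
    hp = HyperParams(**{**DESK_HP, **hp_overrides, "channels": channels, "seed": seed})
    return run_experiment(train_retained, test_retained, test_removed, hp)
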