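# Methods

## Task and model

Every unordered pair of drug mentions in a sentence is a classification
instance with label Advice, Effect, Mechanism, Int, or Negative.  The model
is a three-channel bidirectional LSTM over (a) the token sequence with
relative-distance features and (b, c) depth-first and breadth-first
linearizations of the sentence's dependency tree with depth-difference
features.  Per channel, forward and backward hidden sequences are averaged
position-wise and max-pooled over time; the pooled channel vectors are
concatenated, squashed with tanh, and classified by a softmax layer with
dropout.  The intuition behind the tree channels is that words near the
syntactic root and near the drug nodes carry most of the relational signal,
and that a traversal order puts syntactically related words adjacent even
when they are linearly far apart.

Assumptions worth making explicit:

* one dependency parse per sentence, consumed as CoNLL-U over *collapsed*
  tokens (each drug mention is a single parse token).  The parser is
  external; fragmented parses (multiple roots) are repaired by attaching
  extra roots to the first with a synthetic `dep` relation rather than
  dropping instances, since parser output on biomedical text is imperfect.
* candidate pairs are intra-sentential; anaphora and cross-sentence
  relations are out of scope.
* drug blinding (`DRUG_1`/`DRUG_2`/`DRUG_N`, sentence order decides which
  pair mention is first) is what lets the model generalize across drug
  names; placeholders stay uppercase while every other token is lowercased.

## Parameters

| name | meaning | default |
| --- | --- | --- |
| `dw` | word-embedding dimension | 100 |
| `dp` | distance-code width (bits) | 10 |
| `num` | LSTM hidden units per direction | 300 |
| `rho` | dropout ratio, read as **keep** probability | 0.7 |
| `l2` | L2 coefficient on weights | 0.001 |
| `la` | Adam learning rate | 0.01 |
| `alpha` | per-epoch negative undersampling ratio | 0.5 |
| `beta` | Int oversampling ratio per round | 0.5 |
| `K` | Int oversampling rounds | 6 |
| `batch_size`, `max_epochs`, `clip_norm`, `patience`, `dev_fraction` | loop controls | 64 / 30 / 5.0 / 5 / 0.1 |

The first nine rows are the model's standard configuration; the loop
controls are this package's own defaults, chosen for desk-scale
trainability.  `rho` is ambiguous in common usage ("dropout ratio 0.7"); we
read it as the keep probability (drop 0.3), which trains stably, and expose
`rho_is_keep=False` for the other reading.  Peepholes are diagonal vectors
(the canonical peephole LSTM); `full_peepholes=True` switches to full
matrices.  L2 applies to weight matrices and peephole vectors, not to biases
and not to the embedding table (penalizing embeddings toward zero mostly
hurts rare-word representations).  Parameter averaging keeps a uniform
running average of all parameters across updates and uses it at evaluation
time; it can be disabled.

## Numerical choices

* Distance encoding is sign–magnitude: bit 0 is the sign, bits 1–9 the
  magnitude clamped at 511, most significant first.  This is symmetric
  around zero, preserves `encode(0) = 0`, and covers realistic sentence
  lengths; the clamp absorbs overflow instead of erroring.
* The distance sign convention is `D = drug_position − token_position`, so a
  word left of both drugs has positive distances (this matches the worked
  example: "suggest" gets 5 and 12).
* DFS/BFS tie-break: children are visited in ascending token position.
* Variable-length batches are right-padded with a mask; masked steps pass
  the LSTM state through unchanged and pooling ignores padded positions
  (verified by a padding-invariance test).
* Softmax is computed with max-subtraction; cross-entropy clamps
  probabilities at 1e-12; prediction ties break by the fixed class order
  (Advice, Effect, Mechanism, Int, Negative).
* Gradients are hand-derived BPTT through the averaged Bi-LSTM, max-pooling
  argmax routing, and the dropout/softmax head; they are pinned by a
  finite-difference test at 1e-7 and the step equations by a scalar-loop
  oracle at 1e-10.
* With fixed seeds the entire run (generation, sampling, dropout,
  initialization) is bit-reproducible on one thread.

## Negative filtering

Rule 1 removes same-name pairs (case-insensitive match of the original
mention texts after whitespace normalization).  Rule 2 removes
apposition/exemplification (`DRUG_1 ( DRUG_N* DRUG_2` and
`DRUG_1 such as DRUG_N* DRUG_2`, commas allowed).  Rule 3 removes
coordination: the gap between `DRUG_1` and `DRUG_2` is non-empty and drawn
entirely from {`,`, `and`, `or`, `DRUG_N`} — so in "effects of X, Y, and Z"
both (X, Y) and (X, Z) are removed.  The pattern set is deliberately a small
closed canon: reproducibility is preferred over coverage, and the decision
never reads the instance label.  Report attribution is first-match (1→2→3);
the removal outcome is order-independent.  On the test side, removed
instances are kept in the evaluation universe and scored as
predicted-Negative, so a wrongly filtered positive counts as a false
negative.

## The synthetic corpus

The generator emulates the corpus formats (DDI-XML + CoNLL-U + gold) at desk
scale.  Each sentence has 2–4 drug mentions and one labeled pair; other
pairs are Negative.  The label is a deterministic function of a planted
trigger: a class-lexicon word whose tree node is the parent of both pair
drugs.  Negative sentences either lack trigger words, or (30% of
non-filterable negatives) contain a *distractor* — a trigger word placed
linearly between the drugs but two or more tree levels below them, so the
linear channel sees the same surface cue as a true positive while the depth
features disambiguate.  This is what makes the channel-ablation direction
testable: a linear-only model misclassifies distractor negatives.  20% of
negative sentences instantiate the three filter-rule surface patterns.  The
class mix (75.7% Negative, 8.0/10.2/5.0/1.1% positives) together with the
extra unlabeled pairs yields roughly a 1:5.8 positive:negative instance
ratio with Int rarest, mirroring the benchmark corpus's imbalance.  Trees
are projective by construction (every subtree spans a contiguous token
range).

What the generator does **not** emulate: real lexical variety, multi-trigger
and negated constructions, parser errors, discontinuous mentions, long
coordinate chains, and document-register differences.  Passing the synthetic
learnability test therefore shows the pipeline and optimizer are correct and
that the tree channels add information under controlled conditions; it does
not predict benchmark-corpus F-scores.

## Desk-scale experiment sizes

The learnability experiment trains on 2000 generated sentences (~2800
instances after filtering) and scores 600 held-out sentences, using reduced
width `dw=24, num=24`, 8 epochs — about 10 s per run on one CPU core, 3-seed
median held-out micro-F ≥ 0.9.  Reproducing published corpus-scale results
(overall F ≈ 0.72 on the benchmark test set) requires the DDIExtraction-2013
corpus distribution, external dependency parses for every sentence, the full
`dw=100, num=300` configuration, and hours of training; that experiment is
supported by the same code paths (`preprocess` → `train` → `predict` →
`evaluate` on the corpus files) but is not part of the test suite.

## Known limitations

* The regex tokenizer approximates the original toolkit's tokenization;
  corpora with unusual punctuation may align differently with their parses
  (misalignment raises an error rather than truncating).
* Discontinuous entity spans (`charOffset` with `;`) are rejected.
* Training is single-threaded numpy; it is meant for method study, not
  large-scale runs.
* Early stopping selects on dev micro-F with patience 5; the published
  configuration's exact epoch count/stopping rule is not documented, so
  ablation deltas can only be compared directionally.
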