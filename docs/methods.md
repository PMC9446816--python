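# Methods

## The task and the model

`birelex` classifies the semantic relation between two annotated entity
mentions in a single biomedical sentence into eight types arranged in a
three-level hierarchy:

* level 1 — is a causal relationship expressed? `undirected_link` (no; the
  negative class) vs `directed_link` (yes);
* level 2 — direction of causality: `positive_cause`, `negative_cause`;
* level 3 — an explicit quantity change: under a positive cause,
  `positive_increase` / `negative_decrease`; under a negative cause,
  `positive_decrease` / `negative_increase`.

All eight labels are trained jointly (the head emits 8 scores); the hierarchy
is exposed through `label_parent` and the binary collapse
(`undirected_link → negative`, everything else `→ positive`).

The classifier is a token-level encoder followed by one affine layer over
gathered token vectors. Three head variants differ only in what they gather:
the sequence-start vector (`cls_token`, input H), the two
entity-representative vectors (`two_token`, 2H), or all three
(`three_token`, 3H; concatenation order fixed as CLS, entity1, entity2 —
the order itself is arbitrary but must be stable). The objective is mean
cross-entropy over the 8 classes.

## Input construction

Five strategies turn a sentence with two entity spans into a token sequence
(`encoding.encode`). The key idea of the masked variants is that a
masked-language-model encoder already knows how to summarize the context of
a `[MASK]` position, so replacing an entity with `[MASK]` yields a
contextual vector for the entity that is independent of its (possibly
out-of-vocabulary) surface form. The `two_masked_sentence` layout duplicates
the sentence across a `[SEP]`, masking entity1 in the first copy and entity2
in the second: each copy keeps one original surface form, so no token
information is lost overall, and the copy order encodes the argument order.

Conventions chosen where the layouts leave room:

* a multi-token entity span is replaced by a **single** replacement token,
  so each entity has exactly one representative position;
* roles follow annotation order (entity1 = subject), not textual order;
* `two_sentence_entity_token` *replaces* the spans with `[E1]`/`[E2]`
  (it is the replacement analogue of the masked two-sentence layout, not a
  wrapping one);
* the unmasked entity in each two-sentence copy is left verbatim;
* truncation drops tokens from the tail just before the final `[SEP]`
  (default `max_len` 256); if a representative token or separator would be
  cut the instance raises a `LengthError` rather than degrading silently;
* overlapping or nested entity pairs are rejected at validation, because
  span replacement is ill-defined on overlaps.

Character offsets are 0-based half-open throughout; display label forms
("Positive Cause") are normalized case-insensitively to snake_case.

## Encoder

The encoder is a contract (`model.EncoderContract`): anything that maps a
padded id batch to per-token H-vectors with a parameter dictionary can sit
under the heads. The package ships `TinyTransformerEncoder`, a pre-norm
transformer (token + learned position + segment embeddings; multi-head
self-attention; tanh feed-forward of width 2H; residuals and layer norm;
N(0, 0.02²) seeded init) implemented on a small numpy reverse-mode autodiff
core (`_autograd.py`). Defaults for desk-scale experiments: 2 layers, H=64,
4 heads, dropout 0.1. It is a genuinely trainable encoder, small enough to
fine-tune on a CPU in seconds; it is not pretrained, so absolute scores are
not comparable to results obtained with large pretrained biomedical
encoders (reference dimension checks use H=512, the layer size quoted for
the reference model).

## Training

`training.train` implements standard fine-tuning: AdamW (β₁=0.9, β₂=0.999,
ε=1e-8, decoupled weight decay 0.01 on matrix-shaped parameters only),
learning rate 5e-5 with linear warmup over the first 10% of steps and linear
decay to zero, gradient clipping at global norm 1.0, batch size 16 (eval 64),
up to 10 epochs. After each epoch the model is scored on the evaluation
split; the best epoch by macro F1 (configurable) is restored at the end,
ties breaking toward the earlier epoch. All randomness — initialization,
per-epoch batch order (reshuffled from a per-epoch derived seed), dropout,
fold shuffling — flows from explicit integer seeds, so runs are bit
reproducible.

`training.crossval` runs stratified k-fold cross-validation (k=5 by
default). Stratification is used even though plain k-fold would also be
defensible; the choice is recorded in each fold's split. Per fold, a fresh
tokenizer is fitted on the training portion only (held-out unknown words map
to `[UNK]`) and a fresh seeded encoder is built. Fold summaries report the
mean and **sample** (n−1) standard deviation, formatted `m.mmm (s.sss)`;
k=1 reports sd 0 with `sd_defined=False`.

## Evaluation

`evaluation` computes the confusion matrix (rows = true), per-class
precision `TP/(TP+FP)`, recall `TP/(TP+FN)`, `F1 = 2PR/(P+R)` and support.
Summary precision/recall/F1 are **macro** averages — the unweighted mean of
the eight per-class values reproduces the reference per-class report's
bottom-line 0.852 exactly, whereas support-weighted averaging gives ≈0.879,
which is how the macro convention was fixed. Every 0/0 ratio evaluates to 0
so degenerate folds aggregate cleanly. Displays round to 3 decimals; stored
values keep full precision.

## Synthetic corpus

The generator (`synthetic`) emulates the cue logic the annotation scheme
assumes — the label is decided by the verb's polarity *in context*:
sentences follow `<modifier?> <E1> <verb phrase> <quantity?> <E2> <tail?> .`
with small versioned lexicons (5 positive-causal, 4 negative-causal,
2 ambiguous-causal, 2 neutral verbs; 4 flip modifiers; 4 quantity phrases).
An intervention modifier such as "knockdown of" flips the effective
polarity, so a positive verb under it yields a negative-family label. The
quantity phrase on the object entity selects the third level under the
effective polarity. Labels are sampled first from `class_weights`
(defaulting to the reference corpus's relation-type totals, so the real
class imbalance is emulated) and a consistent cue combination is sampled
second; hence generated labels equal the cue oracle by construction while
frequencies follow the weights.

Defaults: 2000 instances, 200 entity symbols, `negation_rate` 0.3 (share of
causal instances realized via the modifier route), `quantity_rate` 0.2 (the
chance that a non-third-level sentence carries a *distractor* quantity
phrase in its tail, so quantity wording alone does not give the level away),
`oov_fraction_heldout` 0.5 (share of a held-out corpus drawn from an entity
symbol pool disjoint from the training pool).

What the generator does **not** emulate: real lexical variety, word-piece
tokenization effects, multi-relation sentences, annotator disagreement, or
entity mentions whose role must be inferred rather than read off a template.
Passing the synthetic experiments therefore demonstrates that the pipeline
wiring, the input constructions and the optimization are correct and that
masking confers out-of-vocabulary robustness — not that any particular F1 is
attainable on real abstracts.

## Desk-scale experiment sizes

The learnability experiment trains on the generator defaults (2000
instances) with 400 held-out instances (half OOV) for 10 epochs at three
consecutive seeds, and compares the masked-family inputs with the default
input on the same splits. The cross-validation demonstration uses 400
instances with k=5 and the standard 10-epoch configuration; these sizes keep
the full run in the low minutes on one CPU while leaving the conclusions
unchanged at larger n.

## Known limitations

* No adapter ships for loading pretrained transformer checkpoints; the
  encoder contract is the extension point.
* The reference model's 512-vs-768 hidden-size question is left as a
  parameter: H is configurable and nothing hard-codes either value.
* The table reader is deliberately strict (no quoting/escaping); corpora
  with embedded tabs or newlines must be cleaned upstream.
* The generator's compound-label convention (effective polarity chooses the
  parent; the object quantity phrase chooses the child) is one consistent
  reading of the schema; real annotation guidelines may resolve individual
  sentences differently.
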