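"""Fine-tuning harness: AdamW, warmup/decay schedule, best-epoch selection
and stratified k-fold cross-validation.

Training follows the usual transformer fine-tuning recipe: AdamW with
decoupled weight decay, a learning rate that warms up linearly over the first
``warmup_ratio`` of total steps and then decays linearly to zero, gradient
clipping by global norm, and up to ``num_train_epochs`` epochs with the
best-performing epoch (by a configurable evaluation metric, macro F1 by
default) retained.  All randomness — fold shuffling, parameter
initialization, per-epoch batch order, dropout — flows from explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._autograd import Tensor
from .corpus import DEFAULT_SCHEMA, LabelSchema, RelationInstance
from .encoding import (
    MARKER_TOKENS,
    EncodedExample,
    WhitespaceTokenizer,
    encode,
)
from .evaluation import EvalReport, evaluate
from .model import (
    ClassifierModel,
    EncoderContract,
    HeadConfig,
    TinyTransformerEncoder,
    make_batch,
)
from .synthetic import GeneratorConfig, generate_train_heldout

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "EpochRecord",
    "TrainResult",
    "CrossvalResult",
    "AdamW",
    "learning_rate_at",
    "make_folds",
    "train",
    "select_best",
    "crossval",
    "build_model",
    "encode_instances",
    "run_synthetic_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters (transformer fine-tuning defaults)."""

    num_train_epochs: int = 10
    learning_rate: float = 5e-5
    train_batch_size: int = 16
    eval_batch_size: int = 64
    warmup_ratio: float = 0.1
    weight_decay: float = 0.01
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    max_grad_norm: float = 1.0
    seed: int = 0
    selection_metric: str = "macro_f1"

    def __post_init__(self) -> None:
        if self.num_train_epochs < 0:
            raise ValueError("num_train_epochs must be >= 0")
        for name in ("learning_rate", "train_batch_size", "eval_batch_size",
                     "adam_epsilon", "max_grad_norm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.warmup_ratio <= 1.0:
            raise ValueError("warmup_ratio must be in [0, 1]")


@dataclass(frozen=True)
class FoldSplit:
    k: int
    train_indices: np.ndarray
    test_indices: np.ndarray


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    metrics: EvalReport


@dataclass
class TrainResult:
    model: ClassifierModel
    history: list[EpochRecord]
    best_epoch: int | None


def learning_rate_at(step: int, total_steps: int, config: TrainConfig) -> float:
    """Linear warmup to the peak at ``warmup_ratio * total_steps``, then
    linear decay to 0 at ``total_steps``."""
    warmup_steps = int(config.warmup_ratio * total_steps)
    if step < warmup_steps:
        return config.learning_rate * step / max(warmup_steps, 1)
    remaining = max(total_steps - warmup_steps, 1)
    return config.learning_rate * max(total_steps - step, 0) / remaining


class AdamW:
    """AdamW with decoupled weight decay and global-norm gradient clipping.

    Weight decay applies to matrix-shaped parameters only (embeddings and
    projection weights), not to biases or layer-norm gains, following common
    fine-tuning practice.
    """

    def __init__(self, params: dict[str, Tensor], config: TrainConfig) -> None:
        self.params = params
        self.config = config
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def clip_gradients(self) -> float:
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float(np.sum(p.grad ** 2))
        norm = np.sqrt(total)
        if norm > self.config.max_grad_norm:
            scale = self.config.max_grad_norm / (norm + 1e-12)
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale
        return norm

    def step(self, lr: float) -> None:
        cfg = self.config
        self.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for key, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[key] = b1 * self._m[key] + (1 - b1) * p.grad
            v = self._v[key] = b2 * self._v[key] + (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            update = m_hat / (np.sqrt(v_hat) + cfg.adam_epsilon)
            if p.data.ndim >= 2:
                update = update + cfg.weight_decay * p.data
            p.data -= lr * update


def make_folds(labels: Sequence[str], k: int, seed: int) -> list[FoldSplit]:
    """Stratified k-fold partition, deterministic given ``seed``.

    Classes with fewer than ``k`` members trigger a warning and best-effort
    assignment (inherited from the stratified splitter).
    """
    labels = list(labels)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the number of instances {len(labels)}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"a class has fewer than k={k} members; folds are best-effort",
            UserWarning,
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        splits = list(splitter.split(np.zeros(len(labels)), labels))
    return [
        FoldSplit(k=i, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(splits)
    ]


def select_best(history: Sequence[EpochRecord], selection_metric: str) -> int:
    """Index of the best epoch; ties break toward the earlier epoch."""
    if not history:
        raise ValueError("empty history")
    values = [rec.metrics.metric(selection_metric) for rec in history]
    return int(np.argmax(values))  # argmax returns the first maximum


def train(
    model: ClassifierModel,
    train_set: Sequence[EncodedExample],
    eval_set: Sequence[EncodedExample],
    config: TrainConfig,
) -> TrainResult:
    """Fine-tune ``model``; returns it with best-epoch parameters restored.

    One history entry per epoch (mean training loss + evaluation report).
    Aborts on non-finite loss.
    """
    if not train_set:
        raise ValueError("empty train set")
    train_set = list(train_set)
    n_batches = int(np.ceil(len(train_set) / config.train_batch_size))
    total_steps = max(config.num_train_epochs * n_batches, 1)
    optimizer = AdamW(model.parameters(), config)
    history: list[EpochRecord] = []
    best_state = None
    best_value = -np.inf
    step = 0
    for epoch in range(config.num_train_epochs):
        epoch_rng = np.random.default_rng([config.seed, epoch])
        order = epoch_rng.permutation(len(train_set))
        losses = []
        for b in range(n_batches):
            idx = order[b * config.train_batch_size:
                        (b + 1) * config.train_batch_size]
            batch = make_batch([train_set[i] for i in idx],
                               model.tokenizer, model.schema)
            optimizer.zero_grad()
            loss = model.loss(batch, dropout_rng=epoch_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss {loss.data} at epoch {epoch}, "
                    f"batch {b}"
                )
            loss.backward()
            optimizer.clip_gradients()
            optimizer.step(learning_rate_at(step, total_steps, config))
            step += 1
            losses.append(float(loss.data))
        predictions = model.predict_labels(list(eval_set),
                                           config.eval_batch_size)
        report = evaluate([ex.label for ex in eval_set], predictions,
                          model.schema)
        history.append(EpochRecord(epoch, float(np.mean(losses)), report))
        value = report.metric(config.selection_metric)
        if value > best_value:
            best_value = value
            best_state = model.state()
    if best_state is not None:
        model.load_state(best_state)
    best_epoch = (select_best(history, config.selection_metric)
                  if history else None)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# Pipeline assembly and cross-validation
# ---------------------------------------------------------------------------

def encode_instances(
    instances: Sequence[RelationInstance],
    method: str,
    tokenizer,
    max_len: int = 256,
) -> list[EncodedExample]:
    return [encode(inst, method, tokenizer, max_len) for inst in instances]


def build_model(
    train_instances: Sequence[RelationInstance],
    head_variant: str = "two_token",
    hidden_size: int = 64,
    n_layers: int = 2,
    n_heads: int = 4,
    max_len: int = 256,
    seed: int = 0,
    schema: LabelSchema = DEFAULT_SCHEMA,
    encoder_factory: Callable[..., EncoderContract] | None = None,
) -> ClassifierModel:
    """Fit a tokenizer on the training sentences and assemble a classifier.

    The tokenizer vocabulary is closed over the training split (plus special
    and marker tokens); unseen held-out words map to ``[UNK]``.
    """
    tokenizer = WhitespaceTokenizer()
    tokenizer.register_tokens(MARKER_TOKENS)
    tokenizer.fit([inst.sentence for inst in train_instances])
    factory = encoder_factory or TinyTransformerEncoder
    encoder = factory(
        vocab_size=tokenizer.vocab_size,
        hidden_size=hidden_size,
        n_layers=n_layers,
        n_heads=n_heads,
        max_len=max_len,
        seed=seed,
    )
    head = HeadConfig(variant=head_variant, hidden_size=hidden_size,
                      n_classes=len(schema.relation_labels))
    return ClassifierModel(encoder, head, tokenizer, schema, seed=seed)


@dataclass
class CrossvalResult:
    """Per-fold reports plus mean and sample standard deviation."""

    folds: list[TrainResult]
    reports: list[EvalReport]
    metric_names: tuple[str, ...] = (
        "accuracy", "macro_precision", "macro_recall", "macro_f1",
    )
    sd_defined: bool = True

    def mean(self, metric: str) -> float:
        return float(np.mean([r.metric(metric) for r in self.reports]))

    def sd(self, metric: str) -> float:
        values = [r.metric(metric) for r in self.reports]
        if len(values) < 2:
            return 0.0  # undefined for k=1; see sd_defined
        return float(np.std(values, ddof=1))

    def summary(self) -> dict[str, str]:
        """Cells formatted "m.mmm (s.sss)" per metric."""
        return {
            name: f"{self.mean(name):.3f} ({self.sd(name):.3f})"
            for name in self.metric_names
        }


def crossval(
    instances: Sequence[RelationInstance],
    method: str,
    head_variant: str,
    config: TrainConfig,
    k: int = 5,
    hidden_size: int = 64,
    n_layers: int = 2,
    max_len: int = 256,
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> CrossvalResult:
    """k-fold cross-validation of the full pipeline.

    For every fold a fresh tokenizer is fitted on the training portion only
    and a fresh seeded encoder is built, so held-out out-of-vocabulary
    handling is realistic.
    """
    instances = list(instances)
    folds = make_folds([inst.label for inst in instances], k, config.seed)
    results: list[TrainResult] = []
    reports: list[EvalReport] = []
    for fold in folds:
        train_insts = [instances[i] for i in fold.train_indices]
        test_insts = [instances[i] for i in fold.test_indices]
        model = build_model(
            train_insts, head_variant, hidden_size=hidden_size,
            n_layers=n_layers, max_len=max_len,
            seed=config.seed + fold.k, schema=schema,
        )
        train_examples = encode_instances(train_insts, method,
                                          model.tokenizer, max_len)
        test_examples = encode_instances(test_insts, method,
                                         model.tokenizer, max_len)
        fold_config = replace(config, seed=config.seed + fold.k)
        result = train(model, train_examples, test_examples, fold_config)
        results.append(result)
        predictions = model.predict_labels(test_examples,
                                           config.eval_batch_size)
        reports.append(evaluate([ex.label for ex in test_examples],
                                predictions, schema))
    return CrossvalResult(folds=results, reports=reports,
                          sd_defined=k > 1)


def run_synthetic_experiment(
    gen_config: GeneratorConfig,
    method: str,
    head_variant: str,
    train_config: TrainConfig,
    n_heldout: int = 400,
    hidden_size: int = 64,
    n_layers: int = 2,
    max_len: int = 64,
) -> dict:
    """Train on a synthetic corpus, evaluate on a held-out split with OOV
    entity surfaces; returns accuracies and the held-out report."""
    train_pairs, held_pairs = generate_train_heldout(gen_config, n_heldout)
    train_insts = [inst for inst, _ in train_pairs]
    model = build_model(train_insts, head_variant, hidden_size=hidden_size,
                        n_layers=n_layers, max_len=max_len,
                        seed=train_config.seed)
    train_examples = encode_instances(train_insts, method, model.tokenizer,
                                      max_len)
    held_examples = encode_instances([inst for inst, _ in held_pairs],
                                     method, model.tokenizer, max_len)
    result = train(model, train_examples, held_examples, train_config)
    predictions = model.predict_labels(held_examples,
                                       train_config.eval_batch_size)
    report = evaluate([ex.label for ex in held_examples], predictions)
    oov_flags = [cues.oov for _, cues in held_pairs]
    correct = [t == p for t, p in
               zip([ex.label for ex in held_examples], predictions)]
    oov_acc = (float(np.mean([c for c, o in zip(correct, oov_flags) if o]))
               if any(oov_flags) else float("nan"))
    return {
        "result": result,
        "report": report,
        "heldout_accuracy": report.accuracy,
        "oov_accuracy": oov_acc,
        "best_epoch": result.best_epoch,
    }
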