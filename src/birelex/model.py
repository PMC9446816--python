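"""Encoder contract, classification heads and the cross-entropy objective.

The classifier is a token-level encoder followed by a single affine head.
The head reads one, two or three encoder output vectors:

``cls_token``
    the vector at the sequence-start token only (input size H);
``two_token``
    the vectors at the two entity-representative positions, concatenated
    (input size 2H);
``three_token``
    sequence-start plus both representative vectors (input size 3H).

The concatenation order is fixed as (CLS, entity1, entity2).  Output size is
the number of relation classes (8 by default) and the objective is mean
cross-entropy.  Any token-level encoder satisfying :class:`EncoderContract`
can sit underneath; the package ships :class:`TinyTransformerEncoder`, a
small seeded transformer for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import logsumexp

from . import _autograd as ag
from ._autograd import Tensor
from .corpus import DEFAULT_SCHEMA, LabelSchema
from .encoding import EncodedExample, TokenizerContract

__all__ = [
    "HEAD_VARIANTS",
    "EncoderContract",
    "TinyTransformerEncoder",
    "HeadConfig",
    "ClassifierModel",
    "Batch",
    "head_input_dim",
    "gather_features",
    "cross_entropy",
    "make_batch",
]

HEAD_VARIANTS: tuple[str, ...] = ("cls_token", "two_token", "three_token")


def head_input_dim(variant: str, hidden_size: int) -> int:
    """Input dimensionality of the classification head: H, 2H or 3H."""
    if hidden_size <= 0:
        raise ValueError("hidden_size must be positive")
    try:
        factor = {"cls_token": 1, "two_token": 2, "three_token": 3}[variant]
    except KeyError:
        raise ValueError(
            f"unknown head variant: {variant!r}; expected one of {HEAD_VARIANTS}"
        ) from None
    return factor * hidden_size


def gather_features(
    token_vectors: np.ndarray, example: EncodedExample, variant: str
) -> np.ndarray:
    """Gather the head input for one example from its per-token vectors."""
    vectors = np.asarray(token_vectors)
    for index in (example.e1_index, example.e2_index):
        if not 0 <= index < vectors.shape[0]:
            raise IndexError(
                f"representative index {index} out of range for "
                f"{vectors.shape[0]} token vectors"
            )
    if variant == "cls_token":
        parts = [vectors[example.cls_index]]
    elif variant == "two_token":
        parts = [vectors[example.e1_index], vectors[example.e2_index]]
    elif variant == "three_token":
        parts = [vectors[example.cls_index], vectors[example.e1_index],
                 vectors[example.e2_index]]
    else:
        raise ValueError(f"unknown head variant: {variant!r}")
    return np.concatenate(parts)


def cross_entropy(scores: np.ndarray, labels: Sequence[int]) -> float:
    """Mean negative log-softmax of the true class, computed stably."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if labels.ndim == 0:
        labels = labels[None]
    if np.any(labels < 0) or np.any(labels >= scores.shape[1]):
        raise ValueError("label index outside the class range")
    lse = logsumexp(scores, axis=1)
    picked = scores[np.arange(scores.shape[0]), labels]
    return float(np.mean(lse - picked))


# ---------------------------------------------------------------------------
# Encoder contract and the built-in tiny transformer
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Padded id arrays for a list of encoded examples."""

    token_ids: np.ndarray       # (B, T) int
    segment_ids: np.ndarray     # (B, T) int
    attention_mask: np.ndarray  # (B, T) 1.0 = real token, 0.0 = padding
    e1_index: np.ndarray        # (B,) int
    e2_index: np.ndarray        # (B,) int
    label_ids: np.ndarray | None


def make_batch(
    examples: Sequence[EncodedExample],
    tokenizer: TokenizerContract,
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> Batch:
    """Pad a list of encoded examples into rectangular id arrays."""
    max_len = max(len(ex.tokens) for ex in examples)
    pad_id = tokenizer.to_ids([tokenizer.pad_token])[0]
    ids = np.full((len(examples), max_len), pad_id, dtype=np.int64)
    segs = np.zeros((len(examples), max_len), dtype=np.int64)
    mask = np.zeros((len(examples), max_len), dtype=np.float64)
    for i, ex in enumerate(examples):
        n = len(ex.tokens)
        ids[i, :n] = tokenizer.to_ids(ex.tokens)
        segs[i, :n] = ex.segment_ids
        mask[i, :n] = 1.0
    labels = None
    if all(ex.label is not None for ex in examples):
        labels = np.array(
            [schema.label_index(ex.label) for ex in examples], dtype=np.int64
        )
    return Batch(
        token_ids=ids,
        segment_ids=segs,
        attention_mask=mask,
        e1_index=np.array([ex.e1_index for ex in examples], dtype=np.int64),
        e2_index=np.array([ex.e2_index for ex in examples], dtype=np.int64),
        label_ids=labels,
    )


@runtime_checkable
class EncoderContract(Protocol):
    """A token-level encoder: padded id batch -> per-token H-vectors."""

    hidden_size: int

    def forward(self, batch: Batch,
                dropout_rng: np.random.Generator | None = None) -> Tensor: ...

    def parameters(self) -> dict[str, Tensor]: ...


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + 1e-5) ** -0.5 * gain + bias


class TinyTransformerEncoder:
    """A small pre-norm transformer encoder with seeded initialization.

    Token + position + segment embeddings feed ``n_layers`` blocks of
    multi-head self-attention and a tanh feed-forward, each with residual
    connections and layer normalization, followed by a final normalization.
    All parameters are drawn from one seeded generator, so construction and
    the forward pass are fully deterministic.
    """

    def __init__(
        self,
        vocab_size: int,
        hidden_size: int = 64,
        n_layers: int = 2,
        n_heads: int = 4,
        max_len: int = 256,
        seed: int = 0,
        dropout_rate: float = 0.1,
    ) -> None:
        if hidden_size % n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.max_len = max_len
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)

        def param(*shape):
            return Tensor(rng.normal(0.0, 0.02, size=shape),
                          requires_grad=True)

        p: dict[str, Tensor] = {
            "tok_emb": param(vocab_size, hidden_size),
            "pos_emb": param(max_len, hidden_size),
            "seg_emb": param(2, hidden_size),
        }
        for i in range(n_layers):
            for name in ("wq", "wk", "wv", "wo"):
                p[f"l{i}.{name}"] = param(hidden_size, hidden_size)
            p[f"l{i}.ff1"] = param(hidden_size, 2 * hidden_size)
            p[f"l{i}.ff1_b"] = Tensor(np.zeros(2 * hidden_size),
                                      requires_grad=True)
            p[f"l{i}.ff2"] = param(2 * hidden_size, hidden_size)
            p[f"l{i}.ff2_b"] = Tensor(np.zeros(hidden_size),
                                      requires_grad=True)
            for ln in ("ln1", "ln2"):
                p[f"l{i}.{ln}_g"] = Tensor(np.ones(hidden_size),
                                           requires_grad=True)
                p[f"l{i}.{ln}_b"] = Tensor(np.zeros(hidden_size),
                                           requires_grad=True)
        p["ln_f_g"] = Tensor(np.ones(hidden_size), requires_grad=True)
        p["ln_f_b"] = Tensor(np.zeros(hidden_size), requires_grad=True)
        self._params = p

    def parameters(self) -> dict[str, Tensor]:
        return self._params

    def forward(self, batch: Batch,
                dropout_rng: np.random.Generator | None = None) -> Tensor:
        p = self._params
        B, T = batch.token_ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        x = (
            ag.gather_rows(p["tok_emb"], batch.token_ids)
            + ag.gather_rows(p["pos_emb"], np.arange(T))
            + ag.gather_rows(p["seg_emb"], batch.segment_ids)
        )
        # Additive attention bias: padding keys get a large negative score.
        bias = Tensor((1.0 - batch.attention_mask)[:, None, None, :] * -1e9)
        h, d = self.n_heads, self.hidden_size // self.n_heads
        scale = 1.0 / np.sqrt(d)
        for i in range(self.n_layers):
            ln = _layer_norm(x, p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])

            def heads(t: Tensor) -> Tensor:
                return t.reshape(B, T, h, d).transpose(0, 2, 1, 3)

            q = heads(ln @ p[f"l{i}.wq"])
            k = heads(ln @ p[f"l{i}.wk"])
            v = heads(ln @ p[f"l{i}.wv"])
            scores = q @ k.transpose(0, 1, 3, 2) * scale + bias
            att = scores.softmax(axis=-1)
            att = ag.dropout(att, self.dropout_rate, dropout_rng)
            ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, self.hidden_size)
            x = x + ctx @ p[f"l{i}.wo"]
            ln2 = _layer_norm(x, p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
            ff = (ln2 @ p[f"l{i}.ff1"] + p[f"l{i}.ff1_b"]).tanh()
            ff = ag.dropout(ff, self.dropout_rate, dropout_rng)
            x = x + ff @ p[f"l{i}.ff2"] + p[f"l{i}.ff2_b"]
        return _layer_norm(x, p["ln_f_g"], p["ln_f_b"])


# ---------------------------------------------------------------------------
# Head + classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadConfig:
    """Configuration of the affine classification head."""

    variant: str = "two_token"
    hidden_size: int = 64
    n_classes: int = 8
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        head_input_dim(self.variant, self.hidden_size)  # validates
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def input_dim(self) -> int:
        return head_input_dim(self.variant, self.hidden_size)


class ClassifierModel:
    """Encoder + gathered-feature affine head."""

    def __init__(
        self,
        encoder: EncoderContract,
        head: HeadConfig,
        tokenizer: TokenizerContract,
        schema: LabelSchema = DEFAULT_SCHEMA,
        seed: int = 0,
    ) -> None:
        if head.hidden_size != encoder.hidden_size:
            raise ValueError(
                f"head hidden_size {head.hidden_size} != encoder "
                f"hidden_size {encoder.hidden_size}"
            )
        self.encoder = encoder
        self.head = head
        self.tokenizer = tokenizer
        self.schema = schema
        rng = np.random.default_rng(seed)
        self.head_w = Tensor(
            rng.normal(0.0, 0.02, size=(head.input_dim, head.n_classes)),
            requires_grad=True,
        )
        self.head_b = Tensor(np.zeros(head.n_classes), requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        params = dict(self.encoder.parameters())
        params["head.w"] = self.head_w
        params["head.b"] = self.head_b
        return params

    def _gathered(self, hidden: Tensor, batch: Batch) -> Tensor:
        rows = np.arange(batch.token_ids.shape[0])
        parts = []
        if self.head.variant in ("cls_token", "three_token"):
            parts.append(ag.gather_nd(hidden, rows, np.zeros_like(rows)))
        if self.head.variant in ("two_token", "three_token"):
            parts.append(ag.gather_nd(hidden, rows, batch.e1_index))
            parts.append(ag.gather_nd(hidden, rows, batch.e2_index))
        return parts[0] if len(parts) == 1 else ag.concat(parts, axis=-1)

    def forward(self, batch: Batch,
                dropout_rng: np.random.Generator | None = None) -> Tensor:
        hidden = self.encoder.forward(batch, dropout_rng)
        features = self._gathered(hidden, batch)
        features = ag.dropout(features, self.head.dropout_rate, dropout_rng)
        return features @ self.head_w + self.head_b

    def loss(self, batch: Batch,
             dropout_rng: np.random.Generator | None = None) -> Tensor:
        if batch.label_ids is None:
            raise ValueError("batch has no labels")
        logits = self.forward(batch, dropout_rng)
        log_probs = logits.log_softmax(axis=-1)
        rows = np.arange(batch.token_ids.shape[0])
        picked = ag.gather_nd(log_probs, rows, batch.label_ids)
        return -picked.mean()

    def classify(self, examples: Sequence[EncodedExample],
                 batch_size: int = 64) -> np.ndarray:
        """Per-class scores (logits), evaluated without dropout."""
        chunks = []
        for start in range(0, len(examples), batch_size):
            batch = make_batch(examples[start : start + batch_size],
                               self.tokenizer, self.schema)
            chunks.append(self.forward(batch).data)
        return np.concatenate(chunks, axis=0)

    def predict_labels(self, examples: Sequence[EncodedExample],
                       batch_size: int = 64) -> list[str]:
        scores = self.classify(examples, batch_size)
        return [self.schema.relation_labels[i]
                for i in scores.argmax(axis=1)]

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for key, tensor in self.parameters().items():
            tensor.data = state[key].copy()
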