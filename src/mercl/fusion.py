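"""Pairwise cross-modal attention (CMA) fusion and the MLP classifier.

For each ordered modality pair, multi-head attention lets one modality's
sequence attend to another's: the *query* side is the modality being
enriched and the *key/value* side supplies the attended content.  Six
directed results are computed —

    a→v : queries h_v, keys/values h_a       v→a : queries h_a, keys/values h_v
    e→v : queries h_v, keys/values h_e       v→e : queries h_e, keys/values h_v
    e→a : queries h_a, keys/values h_e       a→e : queries h_e, keys/values h_a

— each pooled over its query-time axis to one vector of width D and
concatenated in that fixed order into a 6D-wide fusion vector, which a
one-hidden-layer MLP (ReLU, softmax) maps to emotion-class probabilities.

Attention scores are ``Q K^T / sqrt(d_k)`` per head; a row-softmax converts
them to weights by default (``raw_scores=True`` uses the unnormalized
scores directly, for study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat
from .nn import Module, Linear, Dropout

__all__ = [
    "DIRECTIONS", "MultiHeadAttention", "PairwiseCMA", "FusionOutput",
    "MlpClassifier", "Prediction", "classify",
]

#: fixed concatenation order: (label, query modality, key/value modality)
DIRECTIONS = (
    ("a->v", "video", "audio"),
    ("v->a", "audio", "video"),
    ("e->v", "video", "eeg"),
    ("v->e", "eeg", "video"),
    ("e->a", "audio", "eeg"),
    ("a->e", "eeg", "audio"),
)


class MultiHeadAttention(Module):
    """Multi-head attention with queries and keys/values from two sources."""

    def __init__(self, width: int, n_heads: int = 4, raw_scores: bool = False,
                 rng: np.random.Generator | None = None):
        if width % n_heads != 0:
            raise ValueError(f"width {width} not divisible by {n_heads} heads")
        self.width = width
        self.n_heads = n_heads
        self.d_k = width // n_heads
        self.raw_scores = raw_scores
        self.w_q = Linear(width, width, bias=False, rng=rng)
        self.w_k = Linear(width, width, bias=False, rng=rng)
        self.w_v = Linear(width, width, bias=False, rng=rng)
        self.w_o = Linear(width, width, bias=False, rng=rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_k).swapaxes(1, 2)

    def forward(self, query_source, kv_source, return_weights: bool = False):
        q_in = Tensor.as_tensor(query_source)
        kv_in = Tensor.as_tensor(kv_source)
        squeeze = q_in.ndim == 2
        if squeeze:
            q_in = q_in.reshape(1, *q_in.shape)
            kv_in = kv_in.reshape(1, *kv_in.shape)
        if q_in.shape[-1] != self.width or kv_in.shape[-1] != self.width:
            raise ValueError(
                f"attention width mismatch: expected {self.width}, got "
                f"{q_in.shape[-1]} (query) / {kv_in.shape[-1]} (key-value)")
        q = self._split_heads(self.w_q(q_in))          # (B, H, Tq, dk)
        k = self._split_heads(self.w_k(kv_in))         # (B, H, Tk, dk)
        v = self._split_heads(self.w_v(kv_in))
        scores = (q @ k.transpose_last()) * (1.0 / np.sqrt(self.d_k))
        weights = scores if self.raw_scores else scores.softmax(axis=-1)
        heads = weights @ v                            # (B, H, Tq, dk)
        b, _, tq, _ = heads.shape
        merged = heads.swapaxes(1, 2).reshape(b, tq, self.width)
        out = self.w_o(merged)
        if squeeze:
            out = out[0]
        if return_weights:
            return out, weights.data
        return out


@dataclass
class FusionOutput:
    """The six directed CMA results and their concatenation."""

    results: dict                       # direction label -> pooled (B, D) Tensor
    concatenated: Tensor                # (B, 6D)
    direction_labels: tuple

    @property
    def width(self) -> int:
        return self.concatenated.shape[-1]


class PairwiseCMA(Module):
    """Six directed cross-modal attention blocks with pooling + concat.

    Parameters are independent per direction by default; ``shared=True``
    uses one attention block for all six directions (useful for symmetry
    checks and parameter-tied ablations).
    """

    def __init__(self, width: int, n_heads: int = 4, pooling: str = "mean",
                 raw_scores: bool = False, shared: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if pooling not in ("mean", "last", "max"):
            raise ValueError(f"unknown pooling {pooling!r}")
        self.pooling = pooling
        if shared:
            block = MultiHeadAttention(width, n_heads, raw_scores, rng)
            self.blocks = [block] * len(DIRECTIONS)
        else:
            self.blocks = [MultiHeadAttention(width, n_heads, raw_scores, rng)
                           for _ in DIRECTIONS]
        self.shared = shared

    def parameters(self):
        if self.shared:
            return self.blocks[0].parameters()
        return super().parameters()

    def _pool(self, x: Tensor) -> Tensor:
        if self.pooling == "mean":
            return x.mean(axis=-2)
        if self.pooling == "last":
            return x[:, -1, :]
        # max pooling: subgradient via mask
        mask = (x.data == x.data.max(axis=-2, keepdims=True))
        return (x * mask).sum(axis=-2) / mask.sum(axis=-2)

    def forward(self, h: dict) -> FusionOutput:
        for m in ("video", "audio", "eeg"):
            if m not in h or h[m] is None:
                raise ValueError(f"fusion requires all three modalities; "
                                 f"missing {m!r}")
        h = {m: Tensor.as_tensor(v) for m, v in h.items()}
        results = {}
        pooled = []
        for (label, q_mod, kv_mod), block in zip(DIRECTIONS, self.blocks):
            out = block(h[q_mod], h[kv_mod])
            r = self._pool(out)
            results[label] = r
            pooled.append(r)
        return FusionOutput(results=results, concatenated=concat(pooled, axis=-1),
                            direction_labels=tuple(d[0] for d in DIRECTIONS))


@dataclass
class Prediction:
    probabilities: np.ndarray          # (B, K) rows on the simplex
    labels: np.ndarray                 # (B,) argmax indices
    logits: np.ndarray


class MlpClassifier(Module):
    """Linear → ReLU → dropout → linear; softmax applied at prediction."""

    def __init__(self, in_width: int, n_classes: int, hidden: int = 256,
                 dropout: float = 0.1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.fc1 = Linear(in_width, hidden, rng=rng)
        self.fc2 = Linear(hidden, n_classes, rng=rng)
        self.dropout = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.in_width = in_width
        self.n_classes = n_classes

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.shape[-1] != self.in_width:
            raise ValueError(
                f"classifier expects width {self.in_width}, got {x.shape[-1]}")
        return self.fc2(self.dropout(self.fc1(x).relu()))

    def cross_entropy(self, logits: Tensor, labels) -> Tensor:
        labels = np.asarray(labels, dtype=int)
        logp = logits - logits.data.max(axis=-1, keepdims=True)
        logp = logp - logp.exp().sum(axis=-1, keepdims=True).log()
        onehot = np.zeros(logits.shape)
        onehot[np.arange(labels.size), labels] = 1.0
        return -(logp * onehot).sum() * (1.0 / labels.size)


def classify(fused, mlp: MlpClassifier) -> Prediction:
    """Map a fusion output (or raw feature rows) to class probabilities."""
    x = fused.concatenated if isinstance(fused, FusionOutput) else fused
    logits = mlp(x)
    probs = logits.softmax(axis=-1).data
    return Prediction(probabilities=probs, labels=np.argmax(probs, axis=-1),
                      logits=logits.data)
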