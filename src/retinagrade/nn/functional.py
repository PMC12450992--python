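"""Composite functional operations shared by the model and training code."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, log_softmax, softmax


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C)."""
    return x.mean(axis=(2, 3))


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted categorical cross-entropy on raw logits.

    The per-sample weight is the weight of its true class; the batch loss is
    the weight-normalised mean, so all-equal weights reduce exactly to the
    unweighted mean cross-entropy.
    """
    labels = np.asarray(labels, dtype=np.intp)
    n, k = logits.shape
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(n), labels]
    if class_weights is None:
        return -picked.mean()
    w = np.asarray(class_weights, dtype=logits.data.dtype)[labels]
    return -(picked * Tensor(w)).sum() / float(w.sum())


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: np.ndarray | None = None
                         ) -> tuple[Tensor, Tensor]:
    """softmax(QK^T / sqrt(d_k)) V over the last two axes.

    ``q, k, v`` are (..., T, d_k).  ``key_mask`` is a boolean array over key
    tokens (True = padded/invalid); masked logits are driven to -1e9 before
    the softmax so masked tokens contribute ~0 weight and valid rows still
    sum to 1.  Returns (output, attention weights).
    """
    dk = q.shape[-1]
    scores = (q @ k.swap_last()) * (1.0 / np.sqrt(dk))
    if key_mask is not None:
        bias = np.where(np.asarray(key_mask, bool), -1e9, 0.0).astype(scores.data.dtype)
        scores = scores + Tensor(bias)
    attn = softmax(scores, axis=-1)
    return attn @ v, attn
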