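"""Mask-aware primitives used at both attention levels."""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def masked_softmax(scores: np.ndarray, mask: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax restricted to ``mask == 1`` entries.

    Masked entries get exactly zero weight; unmasked weights sum to 1 along
    ``axis``. Rows whose mask is entirely zero yield an all-zero row (the
    consumer must skip such periods) rather than an error, so fully padded
    slots flow through the network as zeros.
    """
    scores = np.asarray(scores)
    m = np.asarray(mask).astype(bool)
    neg = np.where(m, scores, -np.inf)
    mx = np.max(neg, axis=axis, keepdims=True)
    # all-masked rows have mx == -inf; shift them to 0 to avoid nan
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.exp(neg - mx)
    e = np.where(m, e, 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, e / np.where(denom > 0, denom, 1.0), 0.0)
    return w


def masked_softmax_backward(weights: np.ndarray, dweights: np.ndarray,
                            axis: int = -1) -> np.ndarray:
    """Gradient of masked softmax wrt its scores.

    Masked positions carry zero weight, hence zero score-gradient — the
    standard softmax Jacobian applied to the zero-padded weight vector.
    """
    inner = np.sum(weights * dweights, axis=axis, keepdims=True)
    return weights * (dweights - inner)
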