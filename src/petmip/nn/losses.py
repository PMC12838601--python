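"""Class-weighted binary cross-entropy, in probability and logit form."""

from __future__ import annotations

import numpy as np

PROB_CLAMP = 1e-7
LOGIT_CLAMP = 15.0


def auto_class_weights(labels: np.ndarray) -> dict[int, float]:
    """Inverse-frequency weights w_c = n_total / (2 * n_c)."""
    labels = np.asarray(labels)
    n = labels.size
    weights = {}
    for c in (0, 1):
        n_c = int(np.sum(labels == c))
        if n_c == 0:
            raise ValueError(f"class {c} absent; cannot derive class weights")
        weights[c] = n / (2.0 * n_c)
    return weights


def _resolve_weights(class_weights, labels: np.ndarray) -> np.ndarray:
    if class_weights == "auto":
        class_weights = auto_class_weights(labels)
    if class_weights is None:
        class_weights = {0: 1.0, 1: 1.0}
    return np.where(labels == 1, class_weights[1], class_weights[0])


def weighted_bce(probabilities: np.ndarray, labels: np.ndarray, class_weights=None) -> float:
    """Mean over items of -w_y [y log p + (1-y) log(1-p)], p clamped at 1e-7."""
    p = np.clip(np.asarray(probabilities, dtype=np.float64), PROB_CLAMP, 1 - PROB_CLAMP)
    y = np.asarray(labels)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0 or 1")
    w = _resolve_weights(class_weights, y)
    per_item = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.mean(w * per_item))


def bce_with_logits_grad(
    logits: np.ndarray, labels: np.ndarray, class_weights=None
) -> tuple[float, np.ndarray]:
    """(loss, dL/dlogits) for the mean weighted BCE; logits clamped to +-15."""
    z = np.clip(np.asarray(logits, dtype=np.float64), -LOGIT_CLAMP, LOGIT_CLAMP)
    y = np.asarray(labels)
    w = _resolve_weights(class_weights, y)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = weighted_bce(p, y, class_weights)
    dz = w * (p - y) / y.size
    return loss, dz.astype(np.float32)
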