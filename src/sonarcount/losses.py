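"""Loss terms of the multi-task counting objective, with analytic gradients.

All batch reductions are sums (not means), matching the written forms:

* count loss      ``Lc   = sum_k |c_k - chat_k|``
* AU count loss   ``Lcau = sum_k |c_k - chat_k| * exp(-s_k) + s_k`` where
  ``s_k = log sigma_k^2`` is the predicted log noise variance; with s == 0
  this reduces exactly to Lc, and for a fixed error e the minimizer over s
  is ``s* = ln e`` (the model learns sigma^2 = e).
* ranking loss    ``Lr   = sum_k max(0, p'_k - p_k + eps)`` (hinge; eps = 0)
* IEB loss        ``Lieb = -sum_k log(K_class(k) / K) * |c_k - chat_k|`` —
  an information-entropy-based batch reweighting that upweights samples of
  classes rare within the batch (abundance classes: 1 if c < 50, 2 if
  50 <= c < 150, 3 if c >= 150).

Nine ablation configurations compose these terms (with weight ``lambda`` on
Lieb) and select the data sources (augmented set for v-ix, ranked pairs for
vi-ix) and the initialization chaining between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossParts",
    "AblationSpec",
    "ABLATIONS",
    "count_loss",
    "count_loss_grad",
    "au_count_loss",
    "au_count_loss_grad",
    "ranking_loss",
    "ranking_loss_grad",
    "assign_class",
    "assign_classes",
    "ieb_loss",
    "ieb_sample_weights",
    "ieb_loss_grad",
    "total_loss",
]


@dataclass
class LossParts:
    Lc: float | None = None
    Lcau: float | None = None
    Lr: float | None = None
    Lieb: float | None = None
    total: float = 0.0


@dataclass(frozen=True)
class AblationSpec:
    """Which loss terms and data sources one ablation configuration uses."""

    ablation_id: str
    uses_au: bool
    uses_rank: bool
    uses_ieb: bool
    uses_augmented: bool
    init_from: str | None  # ablation id whose trained weights seed this run


ABLATIONS: dict[str, AblationSpec] = {
    "i": AblationSpec("i", False, False, False, False, None),
    "ii": AblationSpec("ii", False, False, True, False, None),
    "iii": AblationSpec("iii", True, False, False, False, None),
    "iv": AblationSpec("iv", True, False, True, False, None),
    "v": AblationSpec("v", False, False, False, True, "i"),
    "vi": AblationSpec("vi", False, True, False, True, "i"),
    "vii": AblationSpec("vii", False, True, True, True, "ii"),
    "viii": AblationSpec("viii", True, True, False, True, "iii"),
    "ix": AblationSpec("ix", True, True, True, True, "iii"),
}


def _check_lengths(c, chat):
    c = np.asarray(c, dtype=float)
    chat = np.asarray(chat, dtype=float)
    if c.shape != chat.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {chat.shape}")
    if c.size == 0:
        raise ValueError("batch must contain at least one sample")
    return c, chat


def count_loss(c, chat) -> float:
    """L1 count loss, summed over the batch."""
    c, chat = _check_lengths(c, chat)
    return float(np.abs(c - chat).sum())


def count_loss_grad(c, chat) -> np.ndarray:
    """d Lc / d chat (subgradient 0 at exact ties)."""
    c, chat = _check_lengths(c, chat)
    return -np.sign(c - chat)


def au_count_loss(c, chat, s) -> float:
    """Aleatoric-uncertainty weighted count loss (exp(-s) parameterization)."""
    c, chat = _check_lengths(c, chat)
    s = np.asarray(s, dtype=float)
    if s.shape != c.shape:
        raise ValueError(f"length mismatch: s has shape {s.shape}")
    return float((np.abs(c - chat) * np.exp(-s) + s).sum())


def au_count_loss_grad(c, chat, s) -> tuple[np.ndarray, np.ndarray]:
    """(d Lcau / d chat, d Lcau / d s)."""
    c, chat = _check_lengths(c, chat)
    s = np.asarray(s, dtype=float)
    w = np.exp(-s)
    dchat = -np.sign(c - chat) * w
    ds = 1.0 - np.abs(c - chat) * w
    return dchat, ds


def ranking_loss(pair_scores, epsilon: float = 0.0) -> float:
    """Pairwise hinge: sum_k max(0, p'_k - p_k + eps); zero iff all ordered."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    total = 0.0
    for p, p_prime in pair_scores:
        total += max(0.0, p_prime - p + epsilon)
    return float(total)


def ranking_loss_grad(pair_scores, epsilon: float = 0.0):
    """Per-pair (d Lr / d p, d Lr / d p'): (-1, +1) on violated pairs."""
    grads = []
    for p, p_prime in pair_scores:
        if p_prime - p + epsilon > 0:
            grads.append((-1.0, 1.0))
        else:
            grads.append((0.0, 0.0))
    return grads


def assign_class(c: int) -> int:
    """Abundance class: 1 if c < 50, 2 if 50 <= c < 150, 3 if c >= 150."""
    if c < 0:
        raise ValueError(f"count must be >= 0; got {c}")
    if c < 50:
        return 1
    if c < 150:
        return 2
    return 3


def assign_classes(counts) -> np.ndarray:
    return np.array([assign_class(int(c)) for c in np.asarray(counts).ravel()])


def ieb_sample_weights(classes, K: int | None = None) -> np.ndarray:
    """Per-sample weights -log(K_class(k) / K); rarer class => larger weight."""
    classes = np.asarray(classes)
    K = K if K is not None else classes.size
    if classes.size != K:
        raise ValueError("K must equal the number of class labels")
    _, inverse, counts = np.unique(classes, return_inverse=True, return_counts=True)
    return -np.log(counts[inverse] / K)


def ieb_loss(c, chat, classes, K: int | None = None) -> float:
    """Entropy-weighted L1: -sum_k log(K_class(k)/K) |c_k - chat_k|."""
    c, chat = _check_lengths(c, chat)
    classes = np.asarray(classes)
    if classes.shape != c.shape:
        raise ValueError("classes must match the batch length")
    w = ieb_sample_weights(classes, K if K is not None else c.size)
    return float((w * np.abs(c - chat)).sum())


def ieb_loss_grad(c, chat, classes, K: int | None = None) -> np.ndarray:
    c, chat = _check_lengths(c, chat)
    w = ieb_sample_weights(np.asarray(classes), K if K is not None else c.size)
    return -w * np.sign(c - chat)


def total_loss(parts: LossParts, spec: AblationSpec, lam: float = 0.1) -> float:
    """Compose the active terms for one ablation configuration."""
    count_term = parts.Lcau if spec.uses_au else parts.Lc
    if count_term is None:
        needed = "Lcau" if spec.uses_au else "Lc"
        raise ValueError(f"ablation {spec.ablation_id} requires {needed}")
    total = float(count_term)
    if spec.uses_rank:
        if parts.Lr is None:
            raise ValueError(f"ablation {spec.ablation_id} requires Lr")
        total += float(parts.Lr)
    if spec.uses_ieb:
        if parts.Lieb is None:
            raise ValueError(f"ablation {spec.ablation_id} requires Lieb")
        total += lam * float(parts.Lieb)
    parts.total = total
    return total
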