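"""Balanced focal loss for two-class problems, and its cross-entropy limit.

With p the 0/1 ground-truth label, q = 1-p, predicted positive-class
probability p_hat and q_hat = 1-p_hat, the per-sample loss is

    L = -[ beta * q_hat**gamma * p * log(p_hat)
           + (1-beta) * p_hat**gamma * q * log(q_hat) ]

where beta in [0,1] is the class-balance weight and gamma >= 0 the focusing
parameter: the modulating factors q_hat**gamma / p_hat**gamma shrink the loss
of confidently-correct ("easy") samples so training concentrates on hard ones.
At gamma=0, beta=0.5 the loss is exactly half the binary cross-entropy.
Defaults beta=0.25, gamma=2.  Natural logarithm; batch reduction is the mean;
probabilities are clamped to [eps, 1-eps] for stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FocalParams", "CE", "focal_loss", "focal_loss_grad"]


@dataclass(frozen=True)
class FocalParams:
    beta: float = 0.25
    gamma: float = 2.0
    clamp_eps: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


#: cross-entropy as the focal special case (gamma=0) with symmetric class
#: weights; the factor 0.5 relative to plain BCE is absorbed by the learning
#: rate and irrelevant to the optimizer trajectory comparison tests.
CE = FocalParams(beta=0.5, gamma=0.0)


def _clamp(p_hat: np.ndarray, eps: float) -> np.ndarray:
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if np.any(p_hat < 0) or np.any(p_hat > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return np.clip(p_hat, eps, 1.0 - eps)


def focal_loss(p_hat, label, params: FocalParams = FocalParams()) -> float:
    """Mean balanced focal loss of predicted probabilities against 0/1 labels."""
    ph = _clamp(p_hat, params.clamp_eps)
    p = np.asarray(label, dtype=np.float64)
    if p.shape != ph.shape and p.size != ph.size:
        raise ValueError("labels and predictions must have equal length")
    qh = 1.0 - ph
    b, g = params.beta, params.gamma
    per = -(b * qh ** g * p * np.log(ph)
            + (1.0 - b) * ph ** g * (1.0 - p) * np.log(qh))
    return float(np.mean(per))


def focal_loss_grad(p_hat, label,
                    params: FocalParams = FocalParams()) -> np.ndarray:
    """d(mean loss)/d(p_hat), elementwise over the batch."""
    ph = _clamp(p_hat, params.clamp_eps)
    p = np.asarray(label, dtype=np.float64)
    qh = 1.0 - ph
    b, g = params.beta, params.gamma
    # label-1 term: -beta * d/dph [ qh^g * log(ph) ]
    if g == 0:
        d1 = -b / ph
        d0 = (1.0 - b) / qh
    else:
        d1 = -b * (-g * qh ** (g - 1.0) * np.log(ph) + qh ** g / ph)
        d0 = -(1.0 - b) * (g * ph ** (g - 1.0) * np.log(qh) - ph ** g / qh)
    # evaluated at the clamped probability: saturated predictions keep the
    # boundary gradient rather than a flat zero, so training can escape them
    grad = p * d1 + (1.0 - p) * d0
    return grad / ph.size
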