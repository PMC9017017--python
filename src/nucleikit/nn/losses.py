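"""Training losses: cross-entropy, mean squared error, soft Dice."""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    return ag.softmax_cross_entropy(logits, labels)


def mse(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    target = ag._as_tensor(target)
    d = ag.sub(pred, target)
    return ag.tmean(ag.mul(d, d))


def soft_dice(prob: Tensor, target: np.ndarray | Tensor, eps: float = 1.0) -> Tensor:
    """1 - soft Dice of a foreground-probability map against a binary mask.

    ``eps`` smooths the empty-mask case and keeps gradients finite.
    """
    target = ag._as_tensor(target)
    inter = ag.tsum(ag.mul(prob, target))
    denom = ag.add(ag.tsum(prob), ag.tsum(target))
    dice = ag.div(ag.add(ag.mul(inter, ag._as_tensor(2.0)), ag._as_tensor(eps)),
                  ag.add(denom, ag._as_tensor(eps)))
    return ag.sub(ag._as_tensor(1.0), dice)
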