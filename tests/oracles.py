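"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — scalar loops and exhaustive
enumeration — and shares no code with the package internals it checks.
"""
from __future__ import annotations

import itertools

import numpy as np


def conv2d_scalar(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None
                  ) -> np.ndarray:
    """Same-padded stride-1 cross-correlation via explicit quadruple loops.

    x: (n, h, w, cin); w: (kh, kw, cin, cout).
    """
    n, h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, h, wd, cout))
    for bi in range(n):
        for oi in range(h):
            for oj in range(wd):
                for oc in range(cout):
                    acc = 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            ii, jj = oi + ki - ph, oj + kj - pw
                            if 0 <= ii < h and 0 <= jj < wd:
                                for ic in range(cin):
                                    acc += x[bi, ii, jj, ic] * w[ki, kj, ic, oc]
                    out[bi, oi, oj, oc] = acc + (b[oc] if b is not None else 0.0)
    return out


def depthwise_conv2d_scalar(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-channel same-padded convolution; w: (kh, kw, c)."""
    n, h, wd, c = x.shape
    kh, kw, _ = w.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((n, h, wd, c))
    for bi in range(n):
        for oi in range(h):
            for oj in range(wd):
                for ch in range(c):
                    acc = 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            ii, jj = oi + ki - ph, oj + kj - pw
                            if 0 <= ii < h and 0 <= jj < wd:
                                acc += x[bi, ii, jj, ch] * w[ki, kj, ch]
                    out[bi, oi, oj, ch] = acc
    return out


def bn_eval_scalar(x: np.ndarray, gamma, beta, mean, var, eps=1e-5) -> np.ndarray:
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


def recurrent_conv_scalar(x, gamma, beta, mean, var, wf, bf, recs,
                          depthwise=False, eps=1e-5):
    """Hand-unrolled recurrent conv layer: BN -> ReLU -> iterated convolution.

    ``recs`` is the list of per-step recurrent kernels (one entry reused for
    every step models shared weights).
    """
    a = np.maximum(bn_eval_scalar(x, gamma, beta, mean, var, eps), 0.0)
    f = conv2d_scalar(a, wf, bf)
    h = f
    for wr in recs:
        rec = depthwise_conv2d_scalar(h, wr) if depthwise else conv2d_scalar(h, wr)
        h = f + rec
    return h


def best_matching_bruteforce(pred: np.ndarray, gt: np.ndarray, radius: float
                             ) -> int:
    """Maximum one-to-one matching within ``radius`` by exhaustive enumeration.

    Feasible for point sets of up to ~6 entries.
    """
    npred, ngt = len(pred), len(gt)
    if npred == 0 or ngt == 0:
        return 0
    d = np.sqrt(((pred[:, None, :] - gt[None, :, :]) ** 2).sum(-1))
    best = 0
    k = min(npred, ngt)
    for size in range(k, 0, -1):
        for psub in itertools.combinations(range(npred), size):
            for gperm in itertools.permutations(range(ngt), size):
                if all(d[p, q] <= radius for p, q in zip(psub, gperm)):
                    return size
    return best


def auc_pairs(scores: np.ndarray, positive: np.ndarray) -> float:
    """Binary AUC by concordant-pair counting with half-credit for ties."""
    pos = scores[positive.astype(bool)]
    neg = scores[~positive.astype(bool)]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / total


def dice_naive(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    if not a.any() and not b.any():
        return 1.0
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
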