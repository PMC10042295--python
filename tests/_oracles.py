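"""Independent brute-force oracles used only by the tests.

Each function re-derives a quantity by the most literal method available
(nested loops, exhaustive pair counting, closed forms) without sharing
code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def lanczos_direct(grid: np.ndarray, out_w: int, out_h: int,
                   taps: int) -> np.ndarray:
    """Direct (non-separable-code) windowed-sinc resample.

    Same conventions as the implementation contract: half-pixel centers,
    kernel widened by the scale factor on downscale, source indices
    clamped to the edge, per-pixel weight normalization, rounded 8-bit
    output.
    """
    g = np.asarray(grid, dtype=np.float64)
    in_h, in_w = g.shape

    def kernel(x: float, a: int) -> float:
        if abs(x) >= a:
            return 0.0
        if x == 0.0:
            return 1.0
        px = math.pi * x
        return a * math.sin(px) * math.sin(px / a) / (px * px)

    def axis_weights(n_in: int, n_out: int):
        scale = n_in / n_out
        support = max(scale, 1.0)
        rows = []
        for j in range(n_out):
            center = (j + 0.5) * scale - 0.5
            lo = math.ceil(center - taps * support)
            hi = math.floor(center + taps * support)
            pairs = []
            for i in range(lo, hi + 1):
                w = kernel((i - center) / support, taps)
                pairs.append((min(max(i, 0), n_in - 1), w))
            total = sum(w for _, w in pairs)
            rows.append([(i, w / total) for i, w in pairs])
        return rows

    row_w = axis_weights(in_h, out_h)
    col_w = axis_weights(in_w, out_w)
    out = np.zeros((out_h, out_w))
    for r in range(out_h):
        for c in range(out_w):
            acc = 0.0
            for i, wi in row_w[r]:
                for j, wj in col_w[c]:
                    acc += wi * wj * g[i, j]
            out[r, c] = acc
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def mann_whitney_auc(scores, labels) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def augmented_leads(lead_i, lead_ii):
    """All three augmented limb leads from Einthoven's I and II.

    With III = II - I: aVR = -(I+II)/2, aVL = (I-III)/2, aVF = (II+III)/2.
    """
    i = np.asarray(lead_i, dtype=np.float64)
    ii = np.asarray(lead_ii, dtype=np.float64)
    iii = ii - i
    return {
        "aVR": -(i + ii) / 2.0,
        "aVL": (i - iii) / 2.0,
        "aVF": (ii + iii) / 2.0,
    }


def confusion_counts(true_labels, predicted_labels):
    """Literal counting of the four confusion cells (positive = 1)."""
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == 1 and p == 1:
            tp += 1
        elif t == 1 and p == 0:
            fn += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fp += 1
    return tp, tn, fp, fn
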