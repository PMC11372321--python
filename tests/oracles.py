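"""Independent brute-force oracles used to check the implementation.

Deliberately naive: O(n^2) loops and per-threshold recomputation, coded
without reference to the library's vectorized paths.
"""

from __future__ import annotations

import numpy as np


def concordance_auc(scores, labels) -> float:
    """ROC AUC as the exhaustive pairwise concordance probability."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def classify_loop(scores, labels, threshold):
    """Per-record classification loop returning (tp, fn, fp, tn)."""
    tp = fn = fp = tn = 0
    for s, y in zip(scores, labels):
        positive = s * 100.0 >= threshold
        if y == 1 and positive:
            tp += 1
        elif y == 1:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


def brute_force_threshold_search(
    scores, labels, groups, grid_step, min_recall=0.70, min_accuracy=0.50
):
    """Exhaustive scan recomputing Z and the constraints per threshold
    from scratch; returns (best_threshold, best_z) or None if infeasible.

    Ties in Z break toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups, dtype=object)
    keep = (groups == "a") | (groups == "b")
    scores, labels, groups = scores[keep], labels[keep], groups[keep]

    best = None
    n_steps = int(round(100.0 / grid_step))
    for i in range(n_steps + 1):
        th = round(i * grid_step, 10)
        if th > 100.0:
            break
        tp, fn, fp, tn = classify_loop(scores, labels, th)
        recall = tp / (tp + fn)
        accuracy = (tp + tn) / (tp + fn + fp + tn)
        if not (recall >= min_recall and accuracy >= min_accuracy):
            continue
        rates = {}
        for g in ("a", "b"):
            m = groups == g
            gtp, gfn, gfp, gtn = classify_loop(scores[m], labels[m], th)
            rates[g] = (100.0 * gtp / (gtp + gfn), 100.0 * gtn / (gtn + gfp))
        z = abs(rates["a"][0] - rates["b"][0]) + abs(rates["a"][1] - rates["b"][1])
        if best is None or z < best[1] - 1e-12:
            best = (th, z)
    return best
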