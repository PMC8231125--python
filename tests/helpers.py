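"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the GLCM oracle
loops over every pixel, the AUC oracle counts concordant pairs, and the
operating-point oracle enumerates every cutoff under the selection rule.
"""

from __future__ import annotations

import numpy as np

UNIT_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm_counts(pixels, mask, d, phi, levels, symmetric=False):
    """Pair counts by explicit double loop over every pixel."""
    h, w = pixels.shape
    dr, dc = UNIT_OFFSETS[phi]
    dr, dc = dr * d, dc * d
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            counts[pixels[r, c], pixels[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts


def mann_whitney_auc(control, test, orientation="greater_is_positive"):
    """Tie-corrected pair-counting AUC: P(test beats control) + P(tie)/2."""
    control = np.asarray(control, float)
    test = np.asarray(test, float)
    diff = test[:, None] - control[None, :]
    if orientation == "less_is_positive":
        diff = -diff
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return wins / (control.size * test.size)


def enumerate_operating_points(control, test, orientation="greater_is_positive"):
    """(cutoff, sensitivity, specificity) at every candidate cutoff."""
    control = np.asarray(control, float)
    test = np.asarray(test, float)
    pooled = np.unique(np.concatenate([control, test]))
    cutoffs = [-np.inf] + list((pooled[:-1] + pooled[1:]) / 2) + [np.inf]
    points = []
    for c in cutoffs:
        if orientation == "greater_is_positive":
            tp = (test >= c).sum()
            fp = (control >= c).sum()
        else:
            tp = (test <= c).sum()
            fp = (control <= c).sum()
        sens = tp / test.size
        spec = 1.0 - fp / control.size
        points.append((c, sens, spec))
    return points


def brute_force_optimal_point(control, test, orientation="greater_is_positive"):
    """The selection rule applied by exhaustive enumeration.

    Restrict to specificity > 0.5 (fall back to all cutoffs when none
    qualifies), maximize sens + spec, break ties by highest sensitivity
    then lowest cutoff.
    """
    points = enumerate_operating_points(control, test, orientation)
    admissible = [p for p in points if p[2] > 0.5] or points
    best_total = max(s + sp for _, s, sp in admissible)
    best = [p for p in admissible if p[1] + p[2] == best_total]
    best_sens = max(s for _, s, _ in best)
    best = [p for p in best if p[1] == best_sens]
    return min(best, key=lambda p: p[0])
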