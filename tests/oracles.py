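"""Independent brute-force oracles used to cross-check the fast paths.

These deliberately use naive O(n1*n0) double loops and stay independent of
the package implementations they verify.
"""

import numpy as np


def pair_count_auc(y_true, scores):
    """AUC by enumerating all positive/negative pairs (ties count 1/2)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for xp in pos:
        for xn in neg:
            if xp > xn:
                total += 1.0
            elif xp == xn:
                total += 0.5
    return total / (len(pos) * len(neg))


def structural_components_loops(y_true, scores):
    """DeLong placement values V10, V01 by explicit double loops."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]

    def psi(a, b):
        if a > b:
            return 1.0
        if a == b:
            return 0.5
        return 0.0

    v10 = np.array([np.mean([psi(xp, xn) for xn in neg]) for xp in pos])
    v01 = np.array([np.mean([psi(xp, xn) for xp in pos]) for xn in neg])
    return v10, v01


def delong_variance_loops(y_true, scores):
    v10, v01 = structural_components_loops(y_true, scores)
    return np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)


def trapezoid_area(points):
    """Trapezoidal area under an (FPR, TPR) polyline."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
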