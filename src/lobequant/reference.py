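"""Naive reference implementations used only for validation.

Each function here recomputes, by exhaustive enumeration, a quantity
the optimised pipeline computes by other means. They are deliberately
slow and share no code with the modules they check, so agreement on
random instances is meaningful evidence of correctness.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["brute_force_local_maxima", "brute_force_ks_statistic"]


def brute_force_local_maxima(response, params):
    """Exhaustive counterpart of :func:`lobequant.detection.find_local_maxima`.

    Checks every pixel's Chebyshev neighbourhood by explicit loops,
    applies the relative threshold, then greedily enforces the minimum
    Euclidean separation in order of descending value (ties: smaller
    row, then smaller column).
    """
    response = np.asarray(response, dtype=float)
    h, w = response.shape
    rad = max(1, math.floor(params.min_separation / 2))
    threshold = params.abs_threshold_fraction * response.max()
    candidates = []
    for r in range(h):
        for c in range(w):
            v = response[r, c]
            if v < threshold:
                continue
            is_strict = True
            for dr in range(-rad, rad + 1):
                for dc in range(-rad, rad + 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and response[rr, cc] >= v:
                        is_strict = False
                        break
                if not is_strict:
                    break
            if is_strict:
                candidates.append((r, c, float(v)))
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    accepted = []
    for r, c, v in candidates:
        ok = True
        for ar, ac, _ in accepted:
            if (r - ar) ** 2 + (c - ac) ** 2 < params.min_separation**2:
                ok = False
                break
        if ok:
            accepted.append((r, c, v))
    return accepted


def brute_force_ks_statistic(values_a, values_b) -> float:
    """Two-sample KS D by direct pooled-ECDF enumeration.

    Evaluates both empirical CDFs at every pooled data point and takes
    the largest absolute difference.
    """
    a = sorted(float(v) for v in values_a)
    b = sorted(float(v) for v in values_b)
    d = 0.0
    for x in a + b:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d
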