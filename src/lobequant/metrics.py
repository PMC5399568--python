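"""Detection-accuracy metrics against synthetic ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_detections", "precision_recall"]


def match_detections(
    detected_rc: np.ndarray,
    true_rc: np.ndarray,
    tolerance: float,
) -> list[tuple[int, int]]:
    """Optimal one-to-one pairing of detections to true centres.

    Pairs are chosen by minimum total Euclidean distance (Hungarian
    assignment); pairs farther apart than ``tolerance`` are discarded.
    Returns (detected_index, true_index) pairs.
    """
    detected_rc = np.asarray(detected_rc, dtype=float).reshape(-1, 2)
    true_rc = np.asarray(true_rc, dtype=float).reshape(-1, 2)
    if len(detected_rc) == 0 or len(true_rc) == 0:
        return []
    dist = np.linalg.norm(detected_rc[:, None, :] - true_rc[None, :, :], axis=2)
    cost = np.where(dist <= tolerance, dist, 1e9)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= tolerance]


def precision_recall(
    detected_rc: np.ndarray,
    true_rc: np.ndarray,
    tolerance: float,
) -> tuple[float, float, int]:
    """(precision, recall, n_matched) of detections vs ground truth.

    Both are 1.0 when there are neither detections nor true objects.
    """
    detected_rc = np.asarray(detected_rc, dtype=float).reshape(-1, 2)
    true_rc = np.asarray(true_rc, dtype=float).reshape(-1, 2)
    matches = match_detections(detected_rc, true_rc, tolerance)
    n_match = len(matches)
    precision = n_match / len(detected_rc) if len(detected_rc) else 1.0
    recall = n_match / len(true_rc) if len(true_rc) else 1.0
    return precision, recall, n_match
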