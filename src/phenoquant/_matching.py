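"""Greedy matching of detected point sets against ground truth."""

from __future__ import annotations

import numpy as np


def greedy_match(detected: np.ndarray, truth: np.ndarray, radius: float,
                 scale=None) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Match detected points to ground-truth points within ``radius``.

    Pairs are assigned greedily by increasing distance; each point is used
    at most once. ``scale`` optionally weights each coordinate axis (e.g.
    physical voxel sizes) before computing Euclidean distances.

    Returns ``(pairs, unmatched_detected_idx, unmatched_truth_idx)``.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detected.size == 0 or truth.size == 0:
        return ([], np.arange(len(detected) if detected.size else 0),
                np.arange(len(truth) if truth.size else 0))
    if scale is not None:
        scale = np.asarray(scale, dtype=float)
        detected = detected * scale
        truth = truth * scale
    d2 = ((detected[:, None, :] - truth[None, :, :]) ** 2).sum(axis=2)
    order = np.dstack(np.unravel_index(np.argsort(d2, axis=None), d2.shape))[0]
    r2 = radius * radius
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in order:
        if d2[i, j] > r2:
            break
        if i in used_d or j in used_t:
            continue
        pairs.append((int(i), int(j)))
        used_d.add(int(i))
        used_t.add(int(j))
    un_d = np.array([i for i in range(len(detected)) if i not in used_d])
    un_t = np.array([j for j in range(len(truth)) if j not in used_t])
    return pairs, un_d, un_t


def precision_recall_f1(n_matched: int, n_detected: int, n_truth: int
                        ) -> tuple[float, float, float]:
    precision = n_matched / n_detected if n_detected else (1.0 if n_truth == 0 else 0.0)
    recall = n_matched / n_truth if n_truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return precision, recall, f1
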