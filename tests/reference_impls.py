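"""Independent reference implementations used as test oracles.

Deliberately naive (per-pixel loops, exhaustive enumeration) and written
against the published algorithm statements, not against the package code,
so they provide a genuinely independent cross-check.
"""

from __future__ import annotations

import numpy as np


def naive_zhang_suen(img: np.ndarray) -> np.ndarray:
    """Textbook two-subiteration thinning with explicit per-pixel loops.

    Neighbors P2..P9 clockwise from north.  Subiteration 1 deletes p when
    2 <= B <= 6, A == 1, P2*P4*P6 == 0, P4*P6*P8 == 0; subiteration 2 uses
    P2*P4*P8 == 0 and P2*P6*P8 == 0.  Repeats until stable.
    """
    grid = (np.asarray(img) > 0).astype(np.uint8)
    h, w = grid.shape

    def neighbors(r: int, c: int) -> list[int]:
        out = []
        for dr, dc in (
            (-1, 0), (-1, 1), (0, 1), (1, 1),
            (1, 0), (1, -1), (0, -1), (-1, -1),
        ):
            rr, cc = r + dr, c + dc
            out.append(int(grid[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
        return out

    while True:
        changed = False
        for sub in (0, 1):
            to_delete = []
            for r in range(h):
                for c in range(w):
                    if not grid[r, c]:
                        continue
                    p = neighbors(r, c)
                    b = sum(p)
                    if not (2 <= b <= 6):
                        continue
                    ring = p + [p[0]]
                    a = sum(
                        1 for i in range(8) if ring[i] == 0 and ring[i + 1] == 1
                    )
                    if a != 1:
                        continue
                    p2, p4, p6, p8 = p[0], p[2], p[4], p[6]
                    if sub == 0:
                        if p2 * p4 * p6 != 0 or p4 * p6 * p8 != 0:
                            continue
                    else:
                        if p2 * p4 * p8 != 0 or p2 * p6 * p8 != 0:
                            continue
                    to_delete.append((r, c))
            if to_delete:
                changed = True
                for r, c in to_delete:
                    grid[r, c] = 0
        if not changed:
            return grid


def random_blob(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """A random connected blob: union of disks along a short random walk."""
    grid = np.zeros((size, size), dtype=np.uint8)
    pos = np.array([size / 2, size / 2])
    for _ in range(rng.integers(3, 9)):
        rad = rng.uniform(2.0, 5.0)
        yy, xx = np.mgrid[:size, :size]
        grid[(yy - pos[0]) ** 2 + (xx - pos[1]) ** 2 <= rad**2] = 1
        pos = np.clip(
            pos + rng.uniform(-5, 5, size=2), rad + 1, size - rad - 2
        )
    return grid


def brute_force_mask_ap(
    all_scores: list[list[float]],
    all_ious: list[np.ndarray],
    n_truth: int,
    thresholds: list[float],
) -> dict[float, float]:
    """AP per IoU threshold from first principles.

    Inputs are per-image score lists and (n_pred, n_truth) IoU matrices.
    Predictions are processed in global score order; each takes the best
    still-free truth above threshold in its own image.  AP is the mean over
    101 recall levels of the maximum precision at recall >= level, each
    quantity recomputed with explicit loops.
    """
    order = sorted(
        ((s, i, p) for i, scores in enumerate(all_scores) for p, s in enumerate(scores)),
        key=lambda t: -t[0],
    )
    result = {}
    for thr in thresholds:
        free = [set(range(m.shape[1])) for m in all_ious]
        tp_flags = []
        for _, img, p in order:
            mat = all_ious[img]
            best, best_t = 0.0, None
            for t in free[img]:
                if mat[p, t] >= thr and mat[p, t] > best:
                    best, best_t = mat[p, t], t
            if best_t is not None:
                free[img].discard(best_t)
                tp_flags.append(True)
            else:
                tp_flags.append(False)
        precisions, recalls = [], []
        tp = fp = 0
        for flag in tp_flags:
            tp += flag
            fp += not flag
            precisions.append(tp / (tp + fp))
            recalls.append(tp / n_truth if n_truth else 0.0)
        ap = 0.0
        for k in range(101):
            level = k / 100.0
            best = 0.0
            for p, r in zip(precisions, recalls):
                if r >= level and p > best:
                    best = p
            ap += best
        result[thr] = ap / 101.0 if n_truth else 0.0
    return result
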