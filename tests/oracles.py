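"""Independent brute-force oracles used to cross-check the analyses.

Everything here is deliberately naive O(N^2) enumeration, sharing no code
with the package implementation.
"""

from __future__ import annotations

import numpy as np


def min_image_distance_matrix(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise periodic minimum-image distances by direct enumeration."""
    points = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)
    n = points.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d = d - box * np.round(d / box)
            out[i, j] = out[j, i] = float(np.sqrt((d**2).sum()))
    return out


def brute_dbscan(
    points: np.ndarray,
    box: np.ndarray,
    eps: float,
    min_neighbors: int,
    include_border: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Textbook DBSCAN by breadth-first expansion over an O(N^2) neighbor list.

    ``min_neighbors`` counts *other* points within ``eps``.  Returns
    (labels, core_mask); labels use -1 for unclustered points.  Border points
    reachable from several clusters keep the first cluster encountered in
    index order, the same deterministic order the implementation uses.
    """
    n = points.shape[0]
    dists = min_image_distance_matrix(points, box)
    neigh = [np.nonzero((dists[i] <= eps) & (np.arange(n) != i))[0] for i in range(n)]
    core = np.array([len(neigh[i]) >= min_neighbors for i in range(n)])
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            u = queue.pop(0)
            for v in neigh[u]:
                if labels[v] == -1:
                    labels[v] = cid
                    if core[v]:
                        queue.append(v)
        cid += 1
    if not include_border:
        labels = np.where(core, labels, -1)
    return labels, core


def brute_contact_pairs(
    pa: np.ndarray, pb: np.ndarray, box: np.ndarray, cutoff: float
) -> int:
    """Number of cross-group pairs within the periodic cutoff, O(N_a * N_b)."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    box = np.asarray(box, dtype=float)
    count = 0
    for a in pa:
        d = pb - a
        d = d - box * np.round(d / box)
        count += int(np.count_nonzero((d**2).sum(axis=1) <= cutoff**2))
    return count


def same_partition(labels_a: np.ndarray, labels_b: np.ndarray, mask: np.ndarray) -> bool:
    """True when two labelings induce the same partition of ``mask`` points."""
    la = labels_a[mask]
    lb = labels_b[mask]
    forward: dict[int, int] = {}
    backward: dict[int, int] = {}
    for x, y in zip(la, lb):
        if forward.setdefault(int(x), int(y)) != y:
            return False
        if backward.setdefault(int(y), int(x)) != x:
            return False
    return True
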