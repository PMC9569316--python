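"""Independent brute-force oracles used to cross-check the library.

These deliberately re-derive results from first principles (exhaustive
scans, closed forms, Lance-Williams recursion) and share no code with the
implementations they check.
"""

from __future__ import annotations

import numpy as np


def scan_local_maxima(values, min_rel_height: float = 0.10) -> list[int]:
    """Exhaustive scan for positive local maxima (0-based indices).

    For each index, look left and right past any plateau of equal values;
    the index is a maximum if both differing neighbours (or the array edge)
    are lower. Plateaus report their leftmost index. Maxima below
    ``min_rel_height`` of the tallest maximum are dropped.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    cand = []
    for i in range(n):
        if v[i] <= 0:
            continue
        if i > 0 and v[i - 1] == v[i]:
            continue  # not the leftmost point of its plateau
        j = i - 1
        while j >= 0 and v[j] == v[i]:
            j -= 1
        if j >= 0 and v[j] > v[i]:
            continue
        k = i + 1
        while k < n and v[k] == v[i]:
            k += 1
        if k < n and v[k] > v[i]:
            continue
        cand.append(i)
    if not cand:
        return []
    top = max(v[i] for i in cand)
    return [i for i in cand if v[i] >= min_rel_height * top]


def pearson_from_covariance(x, y) -> float:
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    mx, my = x.sum() / n, y.sum() / n
    cov = ((x - mx) * (y - my)).sum() / n
    sx = np.sqrt(((x - mx) ** 2).sum() / n)
    sy = np.sqrt(((y - my) ** 2).sum() / n)
    return cov / (sx * sy)


def ward_linkage_heights(distance_matrix: np.ndarray) -> list[float]:
    """Merge heights of Ward agglomeration via the Lance-Williams update.

    At each step the pair of clusters with the smallest current distance is
    merged; distances to the merged cluster follow
    d(uv,k) = sqrt(((n_u+n_k) d_uk^2 + (n_v+n_k) d_vk^2 - n_k d_uv^2) / (n_u+n_v+n_k)).
    """
    d = {
        (i, j): float(distance_matrix[i, j])
        for i in range(distance_matrix.shape[0])
        for j in range(i + 1, distance_matrix.shape[0])
    }
    sizes = {i: 1 for i in range(distance_matrix.shape[0])}
    next_id = distance_matrix.shape[0]
    heights = []

    def get(a, b):
        return d[(a, b) if a < b else (b, a)]

    while len(sizes) > 1:
        (u, v), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        nu, nv = sizes[u], sizes[v]
        new_d = {}
        for k in sizes:
            if k in (u, v):
                continue
            nk = sizes[k]
            val = np.sqrt(
                ((nu + nk) * get(u, k) ** 2 + (nv + nk) * get(v, k) ** 2 - nk * h**2)
                / (nu + nv + nk)
            )
            new_d[k] = val
        del sizes[u], sizes[v]
        d = {
            (a, b): val
            for (a, b), val in d.items()
            if a not in (u, v) and b not in (u, v)
        }
        for k, val in new_d.items():
            d[(k, next_id) if k < next_id else (next_id, k)] = val
        sizes[next_id] = nu + nv
        next_id += 1
    return heights


def weighted_modularity(edges, partition, nodes) -> float:
    """Modularity of a partition from the definition (weighted)."""
    two_m = sum(2.0 * w for _, _, w in edges)
    if two_m == 0:
        return float("nan")
    degree = {n: 0.0 for n in nodes}
    for u, v, w in edges:
        degree[u] += w
        degree[v] += w
    q = 0.0
    for u, v, w in edges:
        if partition[u] == partition[v]:
            q += 2.0 * w / two_m
    for c in set(partition.values()):
        s = sum(degree[n] for n in nodes if partition[n] == c)
        q -= (s / two_m) ** 2
    return q
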