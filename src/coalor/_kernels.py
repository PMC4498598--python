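"""Numba-compiled inner loops for the coalescent simulator.

These kernels consume pre-drawn random variates so that all randomness stays
under the caller's ``numpy.random.Generator`` and results are reproducible
bit-for-bit from a seed.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def kingman_merge(n, waits, u_first, u_second):  # pragma: no cover - jitted
    """Build a Kingman topology by successive pair merges.

    Parameters are pre-drawn variates: ``waits[s]`` is the exponential
    inter-coalescence time while ``n - s`` lineages are active, and
    ``u_first``/``u_second`` are Uniform(0,1) draws used to pick the merging
    pair uniformly among unordered pairs.

    Returns (node_time, parent, children); leaves are nodes ``0..n-1``,
    internal node ``n + s`` is created at merge step ``s``, the root is
    ``2n - 2`` and has parent ``-1``.
    """
    m = 2 * n - 1
    node_time = np.zeros(m, dtype=np.float64)
    parent = np.full(m, -1, dtype=np.int32)
    children = np.empty((n - 1, 2), dtype=np.int32)

    active = np.empty(n, dtype=np.int32)
    for i in range(n):
        active[i] = i

    t = 0.0
    k = n
    for s in range(n - 1):
        t += waits[s]
        i1 = int(u_first[s] * k)
        if i1 >= k:
            i1 = k - 1
        a = active[i1]
        active[i1] = active[k - 1]
        i2 = int(u_second[s] * (k - 1))
        if i2 >= k - 1:
            i2 = k - 2
        b = active[i2]
        new = n + s
        active[i2] = new
        parent[a] = new
        parent[b] = new
        children[s, 0] = a
        children[s, 1] = b
        node_time[new] = t
        k -= 1
    return node_time, parent, children


@numba.njit(cache=True)
def leaf_interval_labels(n, children):  # pragma: no cover - jitted
    """Label every node with a contiguous leaf interval of a planar tour.

    Returns ``(size, lo, hi, tour)`` where ``size[v]`` is the number of leaf
    descendants of ``v``, the leaves below ``v`` occupy tour positions
    ``lo[v]:hi[v]``, and ``tour[p]`` is the leaf id at position ``p``.  One
    O(n) pass per tree; carrier sets of all branches are then slices.
    """
    m = 2 * n - 1
    size = np.ones(m, dtype=np.int32)
    for s in range(n - 1):
        size[n + s] = size[children[s, 0]] + size[children[s, 1]]

    lo = np.zeros(m, dtype=np.int32)
    hi = np.zeros(m, dtype=np.int32)
    tour = np.empty(n, dtype=np.int32)
    root = m - 1
    lo[root] = 0
    hi[root] = n
    stack = np.empty(m, dtype=np.int32)
    stack[0] = root
    sp = 1
    while sp > 0:
        sp -= 1
        v = stack[sp]
        if v < n:
            tour[lo[v]] = v
            continue
        c0 = children[v - n, 0]
        c1 = children[v - n, 1]
        lo[c0] = lo[v]
        hi[c0] = lo[v] + size[c0]
        lo[c1] = hi[c0]
        hi[c1] = hi[v]
        stack[sp] = c0
        stack[sp + 1] = c1
        sp += 2
    return size, lo, hi, tour
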