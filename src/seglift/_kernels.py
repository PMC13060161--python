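"""Numba kernels for the unlinked Wright–Fisher hot path.

The sequential parent sampler mirrors soft selection with an offspring cap:
parent slots are filled in order (offspring-major, two slots each), each draw
fitness-proportional among parents still under quota. A Fenwick (binary
indexed) tree over the fitness weights makes each draw O(log N) and removes a
parent's mass the moment it fills its quota, which is distributionally
identical to rejecting over-quota draws and redrawing among under-quota
parents. The two parents of one offspring are kept distinct by masking the
first parent's weight while drawing the second.

All kernels use numba's internal RNG; callers must seed it via
:func:`seed_kernel_rng` (the simulator derives one sub-seed per generation
from its master generator, so runs are reproducible end to end).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "seed_kernel_rng",
    "scores_kernel",
    "sample_parents_kernel",
    "mendel_transmit_kernel",
]


@njit(cache=True)
def seed_kernel_rng(seed: np.uint32) -> None:
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def scores_kernel(geno: np.ndarray, base: float, beta: np.ndarray,
                  gamma: np.ndarray) -> np.ndarray:
    """Seasonal scores from a dosage matrix.

    Per-locus contributions are decomposed as c(g) = c0 + beta*g + gamma*[g==1];
    ``base`` carries the summed c0 terms plus any constant contribution of
    fixed loci.
    """
    n, L = geno.shape
    z = np.empty(n)
    for i in range(n):
        zi = base
        for l in range(L):
            g = geno[i, l]
            if g == 1:
                zi += beta[l] + gamma[l]
            elif g == 2:
                zi += 2.0 * beta[l]
        z[i] = zi
    return z


@njit(cache=True)
def _fenwick_build(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    tree = np.zeros(n + 1)
    for i in range(1, n + 1):
        tree[i] += w[i - 1]
        j = i + (i & (-i))
        if j <= n:
            tree[j] += tree[i]
    return tree


@njit(cache=True)
def _fenwick_add(tree: np.ndarray, i: int, delta: float) -> None:
    n = tree.shape[0] - 1
    j = i + 1
    while j <= n:
        tree[j] += delta
        j += j & (-j)


@njit(cache=True)
def _fenwick_total(tree: np.ndarray) -> float:
    n = tree.shape[0] - 1
    total = 0.0
    j = n
    while j > 0:
        total += tree[j]
        j -= j & (-j)
    return total


@njit(cache=True)
def _fenwick_search(tree: np.ndarray, u: float) -> int:
    """Smallest index i with cumulative weight(0..i) > u."""
    n = tree.shape[0] - 1
    pos = 0
    bit = 1
    while bit * 2 <= n:
        bit *= 2
    while bit > 0:
        nxt = pos + bit
        if nxt <= n and tree[nxt] <= u:
            u -= tree[nxt]
            pos = nxt
        bit //= 2
    return min(pos, n - 1)


@njit(cache=True)
def sample_parents_kernel(w: np.ndarray, n_offspring: int, cap: int) -> np.ndarray:
    """Fill ``(n_offspring, 2)`` parent slots sequentially.

    ``cap <= 0`` means uncapped. Raises (via a negative sentinel check in the
    caller) if the weights cannot supply the slots.
    """
    n = w.shape[0]
    tree = _fenwick_build(w)
    counts = np.zeros(n, np.int64)
    parents = np.full((n_offspring, 2), -1, np.int64)
    for i in range(n_offspring):
        # first parent
        total = _fenwick_total(tree)
        if total <= 0.0:
            parents[i, 0] = -1
            return parents
        p0 = _fenwick_search(tree, np.random.random() * total)
        counts[p0] += 1
        if cap > 0 and counts[p0] >= cap:
            _fenwick_add(tree, p0, -w[p0])
        # second parent, distinct from the first
        w0 = w[p0] if (cap <= 0 or counts[p0] < cap) else 0.0
        if w0 > 0.0:
            _fenwick_add(tree, p0, -w0)
        total = _fenwick_total(tree)
        if total <= 0.0:
            parents[i, 0] = -1
            return parents
        p1 = _fenwick_search(tree, np.random.random() * total)
        if w0 > 0.0:
            _fenwick_add(tree, p0, w0)
        counts[p1] += 1
        if cap > 0 and counts[p1] >= cap:
            _fenwick_add(tree, p1, -w[p1])
        parents[i, 0] = p0
        parents[i, 1] = p1
    return parents


_TWO53 = 9007199254740992.0  # 2**53: doubles from random() carry 53 fair bits


@njit(cache=True)
def mendel_transmit_kernel(geno: np.ndarray, parents: np.ndarray):
    """Offspring dosages under independent assortment.

    Homozygous parents transmit their allele deterministically; heterozygotes
    transmit a fair Mendelian coin per locus (bits harvested 53 at a time
    from one uniform double). Returns ``(child, column_sums)`` so callers get
    allele counts per locus without a second pass.
    """
    n_off = parents.shape[0]
    L = geno.shape[1]
    child = np.empty((n_off, L), np.uint8)
    colsum = np.zeros(L, np.int64)
    pool = np.int64(0)
    nbits = 0
    for i in range(n_off):
        p0 = parents[i, 0]
        p1 = parents[i, 1]
        for l in range(L):
            g0 = geno[p0, l]
            if g0 == 1:
                if nbits == 0:
                    pool = np.int64(np.random.random() * _TWO53)
                    nbits = 53
                a0 = pool & 1
                pool >>= 1
                nbits -= 1
            else:
                a0 = g0 >> 1
            g1 = geno[p1, l]
            if g1 == 1:
                if nbits == 0:
                    pool = np.int64(np.random.random() * _TWO53)
                    nbits = 53
                a1 = pool & 1
                pool >>= 1
                nbits -= 1
            else:
                a1 = g1 >> 1
            c = a0 + a1
            child[i, l] = c
            colsum[l] += c
    return child, colsum
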