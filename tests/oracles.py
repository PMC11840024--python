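"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops, no
shared code with the package) so it can serve as an oracle for the
vectorized implementations.
"""
from __future__ import annotations

import numpy as np


def oracle_condfdr_grid(p1, p2, edges, floor=30):
    """Double-loop subset counting version of the conditional-FDR grid."""
    lx = [min(max(-np.log10(v), 0.0), 10.0) for v in p1]
    ly = [min(max(-np.log10(v), 0.0), 10.0) for v in p2]
    k = len(edges)
    vals = [[0.0] * k for _ in range(k)]
    for j in range(k):
        n_j = sum(1 for y in ly if y >= edges[j])
        if n_j == 0:
            for i in range(k):
                vals[i][j] = vals[i][j - 1]
            continue
        last = 1.0
        for i in range(k):
            cnt = sum(1 for x, y in zip(lx, ly)
                      if x >= edges[i] and y >= edges[j])
            if cnt >= floor or i == 0:
                last = min(1.0, (10.0 ** -edges[i]) * n_j / cnt) if cnt else 1.0
            vals[i][j] = last
        cur = 1.0
        for i in range(k):
            cur = min(cur, vals[i][j])
            vals[i][j] = cur
    return np.array(vals)


def oracle_interval_overlap(a, b):
    """All-pairs intersection flags: a, b are lists of (chrom, start, end)."""
    flags = []
    for ca, sa, ea in a:
        hit = False
        for cb, sb, eb in b:
            if ca == cb and sa <= eb and sb <= ea:
                hit = True
        flags.append(hit)
    return flags


def oracle_merge_components(intervals):
    """Number of connected components under interval overlap (O(n^2))."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si <= ej and sj <= ei:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def oracle_ld_score(block_sizes, r):
    """Row sums of squared correlations over an explicit block matrix."""
    out = []
    for size in block_sizes:
        mat = np.full((size, size), r)
        np.fill_diagonal(mat, 1.0)
        out.extend((mat ** 2).sum(axis=1))
    return np.array(out)


def oracle_greedy_independent(conjfdr, labels, r, sig, r2_threshold):
    """Reference greedy thinning by ascending conjFDR with block LD."""
    order = sorted(range(len(conjfdr)), key=lambda i: (conjfdr[i], i))
    chosen = []
    for i in order:
        if conjfdr[i] >= sig:
            continue
        dependent = any(
            labels[i] == labels[j] and r ** 2 >= r2_threshold for j in chosen
        )
        if not dependent:
            chosen.append(i)
    return sorted(chosen)
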