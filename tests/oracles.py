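"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from scratch against the same
mathematical definitions, without importing the corresponding package code
paths, so that tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import math

import numpy as np


def irls_huber_oracle(x, y, c=1.345, tol=1e-10, max_iter=500):
    """Straightforward Huber IRLS for a straight line, coded independently.

    Weighted solves go through an explicit 2x2 normal-equation system; scale
    is MAD about the median divided by 0.6745, re-estimated every iteration.
    Returns (slope, intercept, weights).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    w = np.ones(n)

    def solve(w):
        X = np.column_stack([x, np.ones(n)])
        A = (X * w[:, None]).T @ X
        b = (X * w[:, None]).T @ y
        sol = np.linalg.solve(A, b)
        return sol[0], sol[1]

    a, b = solve(w)
    for _ in range(max_iter):
        e = y - a * x - b
        s = np.median(np.abs(e - np.median(e))) / 0.6745
        if s == 0:
            return a, b, np.ones(n)
        r = np.abs(e) / s
        w = np.minimum(1.0, c / np.where(r > 0, r, np.inf))
        a2, b2 = solve(w)
        if max(abs(a2 - a), abs(b2 - b)) < tol:
            a, b = a2, b2
            break
        a, b = a2, b2
    return a, b, w


def hypergeom_tail_enumeration(k, n, K, N):
    """P(X >= k) by direct summation of the hypergeometric pmf with math.comb."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_stepup_by_hand(pvalues):
    """Benjamini-Hochberg step-up spelled out literally."""
    p = list(pvalues)
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def percentile_linear_by_hand(values, q):
    """q-th percentile with linear interpolation, written out explicitly."""
    v = sorted(values)
    n = len(v)
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


class UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_by_union_find(nodes, edges, min_size=1):
    """Connected components via union-find."""
    uf = UnionFind(list(nodes))
    for u, v in edges:
        uf.union(u, v)
    groups = {}
    for v in nodes:
        groups.setdefault(uf.find(v), set()).add(v)
    return [c for c in groups.values() if len(c) >= min_size]


def dcsbm_dl_vectorized(edges, degrees, n_vertices, masks):
    """DC-SBM description length for many 2-partitions at once.

    ``masks`` is an integer array whose bit i gives the block of vertex i.
    Re-implements the objective: S = -E - sum ln k_i! - 1/2 sum e_rs
    ln(e_rs/(e_r e_s)), plus E*h(B(B+1)/2E) + N ln B with B the number of
    non-empty blocks.
    """
    masks = np.asarray(masks, dtype=np.int64)
    E = len(edges)
    lnkfact = sum(math.lgamma(k + 1) for k in degrees)

    bits = [(masks >> i) & 1 for i in range(n_vertices)]
    e11 = np.zeros(len(masks), dtype=np.int64)
    e00 = np.zeros(len(masks), dtype=np.int64)
    for u, v in edges:
        both1 = bits[u] & bits[v]
        both0 = (1 - bits[u]) & (1 - bits[v])
        e11 += both1
        e00 += both0
    e01 = E - e11 - e00

    d1 = np.zeros(len(masks), dtype=np.int64)
    n1 = np.zeros(len(masks), dtype=np.int64)
    for i, k in enumerate(degrees):
        d1 += bits[i] * k
        n1 += bits[i]
    d0 = sum(degrees) - d1
    n0 = n_vertices - n1

    def xlog(a, b):  # a * ln(a/b), 0 where a == 0
        a = a.astype(float)
        b = b.astype(float)
        out = np.zeros_like(a)
        ok = (a > 0) & (b > 0)
        out[ok] = a[ok] * np.log(a[ok] / b[ok])
        return out

    # half-edge counts: e_rr doubled, e_01 appears twice in the sum
    s_term = (
        xlog(2 * e00, d0 * d0)
        + xlog(2 * e11, d1 * d1)
        + 2 * xlog(e01, d0 * d1)
    )
    S = -E - lnkfact - 0.5 * s_term

    def h(x):
        out = np.zeros_like(x)
        ok = x > 0
        out[ok] = (1 + x[ok]) * np.log1p(x[ok]) - x[ok] * np.log(x[ok])
        return out

    b_eff = np.where((n0 > 0) & (n1 > 0), 2, 1)
    L = E * h(b_eff * (b_eff + 1) / (2.0 * E)) + n_vertices * np.log(b_eff)
    return S + L


def weighted_pearson_by_hand(x, y, w):
    """Weighted Pearson written without shortcuts."""
    w = np.asarray(w, float)
    wn = w / w.sum()
    xb = float(np.dot(wn, x))
    yb = float(np.dot(wn, y))
    cov = float(np.dot(wn, (x - xb) * (y - yb)))
    vx = float(np.dot(wn, (x - xb) ** 2))
    vy = float(np.dot(wn, (y - yb) ** 2))
    return cov / math.sqrt(vx * vy)
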