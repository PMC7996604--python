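"""Pairwise metabolite correlation graphs and block-model partitioning.

Pairwise robust correlations are computed on the pooled sample matrix (both
fluids, both groups; one row per (subject, fluid) profile).  Edges passing a
significance/sign rule form an undirected weighted graph.  The graph is
partitioned into blocks with a flat degree-corrected stochastic block model
(DC-SBM) by minimising a microcanonical description length, and the most
strongly correlated structure is exposed through percentile subgraphs and
connected components.

Description length of a simple undirected graph under a partition b:

    S  = -E - sum_i ln(k_i!) - 1/2 sum_rs e_rs ln(e_rs / (e_r e_s))
    L  = E h(B(B+1) / 2E) + N ln B        with h(x) = (1+x)ln(1+x) - x ln x
    DL = S + L   (nats)

where e_rs counts half-edges between blocks r and s (e_rr twice the internal
edges), e_r is the total degree of block r and B the number of non-empty
blocks.  S is the sparse DC-SBM ensemble entropy; L prices the partition and
the block-pair edge counts, so splitting an unstructured graph is penalised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from crossfluid.errors import ParameterError
from crossfluid.robust import (
    DEFAULT_TUNING,
    huber_irls,
    huber_slope_pvalue,
    weighted_correlation,
)
from crossfluid.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    UndefinedCorrelationError,
)


def pairwise_correlations(
    metabolites: list[str],
    values: np.ndarray,
    tuning_const: float = DEFAULT_TUNING,
) -> pd.DataFrame:
    """Huber-weighted correlation for every unordered metabolite pair.

    ``values`` is the pooled ln matrix [profiles x metabolites].  Pairs with
    fewer than 3 complete observations (or a degenerate design) are emitted
    with NaN statistics and valid=False rather than dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] != len(metabolites):
        raise ParameterError("values width must equal number of metabolites")
    rows = []
    m = len(metabolites)
    finite = np.isfinite(values)
    for a in range(m):
        xa = values[:, a]
        for b in range(a + 1, m):
            yb = values[:, b]
            ok = finite[:, a] & finite[:, b]
            n = int(ok.sum())
            rec = {
                "m1": metabolites[a],
                "m2": metabolites[b],
                "weight": np.nan,
                "p": np.nan,
                "n_obs": n,
                "valid": False,
            }
            if n >= 3:
                x, y = xa[ok], yb[ok]
                try:
                    fit = huber_irls(x, y, tuning_const=tuning_const)
                    r = weighted_correlation(x, y, fit.weights)
                    rec.update(
                        weight=r, p=huber_slope_pvalue(fit, x, y, tuning_const), valid=True
                    )
                except (DegenerateDesignError, UndefinedCorrelationError, InsufficientDataError):
                    pass
            rows.append(rec)
    return pd.DataFrame(rows)


def build_graph(
    pairs: pd.DataFrame,
    edge_alpha: float = 0.05,
    positive_only: bool = True,
    use_abs: bool = False,
    vertices: list[str] | None = None,
) -> nx.Graph:
    """Correlation graph: edge iff p < edge_alpha and the sign rule holds.

    Default rule keeps positive correlations only; ``use_abs`` switches to
    |weight| with the absolute value stored as the weight.  All metabolites
    appear as vertices, including isolated ones.
    """
    g = nx.Graph()
    if vertices is None:
        vertices = sorted(set(pairs["m1"]) | set(pairs["m2"]))
    g.add_nodes_from(vertices)
    for rec in pairs.itertuples(index=False):
        if not rec.valid or not np.isfinite(rec.weight):
            continue
        w = abs(rec.weight) if use_abs else rec.weight
        if rec.p < edge_alpha and (w > 0 if (positive_only or use_abs) else True):
            g.add_edge(rec.m1, rec.m2, weight=float(w), p=float(rec.p))
    return g


# ---------------------------------------------------------------------------
# DC-SBM description length


def _h(x: float) -> float:
    if x <= 0:
        return 0.0
    return (1.0 + x) * math.log1p(x) - x * math.log(x)


class _BlockState:
    """Mutable block bookkeeping for greedy DL minimisation."""

    def __init__(self, graph: nx.Graph, labels: np.ndarray, n_blocks: int):
        self.nodes = list(graph.nodes())
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.adj = [
            np.array([self.index[u] for u in graph.neighbors(v)], dtype=int)
            for v in self.nodes
        ]
        self.deg = np.array([graph.degree(v) for v in self.nodes], dtype=int)
        self.E = graph.number_of_edges()
        self.N = len(self.nodes)
        self.B = n_blocks
        self.lnkfact = float(sum(math.lgamma(k + 1) for k in self.deg))
        self.labels = labels.astype(int).copy()
        self.e = np.zeros((n_blocks, n_blocks), dtype=float)  # half-edge counts
        for u, v in graph.edges():
            r, s = self.labels[self.index[u]], self.labels[self.index[v]]
            self.e[r, s] += 1
            self.e[s, r] += 1
        self.er = self.e.sum(axis=1)
        self.nr = np.bincount(self.labels, minlength=n_blocks).astype(float)

    def description_length(self) -> float:
        if self.E == 0:
            return 0.0
        s_term = 0.0
        for r in range(self.B):
            if self.er[r] == 0:
                continue
            for s in range(self.B):
                ers = self.e[r, s]
                if ers > 0 and self.er[s] > 0:
                    s_term += ers * math.log(ers / (self.er[r] * self.er[s]))
        S = -self.E - self.lnkfact - 0.5 * s_term
        b_eff = int((self.nr > 0).sum())
        L = self.E * _h(b_eff * (b_eff + 1) / (2.0 * self.E)) + self.N * math.log(b_eff)
        return S + L

    def neighbor_block_counts(self, i: int) -> np.ndarray:
        return np.bincount(self.labels[self.adj[i]], minlength=self.B).astype(float)

    def move(self, i: int, s: int) -> None:
        r = self.labels[i]
        if r == s:
            return
        d = self.neighbor_block_counts(i)
        for c in range(self.B):
            if c == r or c == s:
                continue
            self.e[r, c] -= d[c]
            self.e[c, r] -= d[c]
            self.e[s, c] += d[c]
            self.e[c, s] += d[c]
        self.e[r, r] -= 2.0 * d[r]
        self.e[r, s] += d[r] - d[s]
        self.e[s, r] += d[r] - d[s]
        self.e[s, s] += 2.0 * d[s]
        self.er[r] -= self.deg[i]
        self.er[s] += self.deg[i]
        self.nr[r] -= 1
        self.nr[s] += 1
        self.labels[i] = s


def description_length(graph: nx.Graph, labels: dict, n_blocks: int | None = None) -> float:
    """DL of an explicit partition (labels: vertex -> 0-based block)."""
    nodes = list(graph.nodes())
    lab = np.array([labels[v] for v in nodes], dtype=int)
    b = n_blocks if n_blocks is not None else int(lab.max()) + 1
    return _BlockState(graph, lab, b).description_length()


def fit_dcsbm(
    graph: nx.Graph,
    n_blocks: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[dict, float]:
    """Greedy DL minimisation with seeded random restarts.

    Each restart starts from a uniform random assignment into ``n_blocks``
    groups and sweeps vertices in random order, applying the single best
    strictly-improving move per vertex until a full sweep makes no move.
    Returns the best (vertex -> block, description length) found; blocks may
    end up empty, so the effective number of blocks is <= n_blocks.
    """
    if n_blocks < 1:
        raise ParameterError("n_blocks must be >= 1")
    nodes = list(graph.nodes())
    if graph.number_of_edges() == 0:
        return {v: 0 for v in nodes}, 0.0
    rng = np.random.default_rng(seed)

    best_labels: np.ndarray | None = None
    best_dl = math.inf
    for _ in range(max(1, n_restarts)):
        labels = rng.integers(0, n_blocks, size=len(nodes))
        state = _BlockState(graph, labels, n_blocks)
        dl = state.description_length()
        improved = True
        while improved:
            improved = False
            order = rng.permutation(len(nodes))
            for i in order:
                r = state.labels[i]
                best_move, best_move_dl = r, dl
                for s in range(n_blocks):
                    if s == r:
                        continue
                    state.move(i, s)
                    cand = state.description_length()
                    state.move(i, r)
                    if cand < best_move_dl - 1e-12:
                        best_move, best_move_dl = s, cand
                if best_move != r:
                    state.move(i, best_move)
                    assert best_move_dl <= dl  # greedy moves never increase DL
                    dl = best_move_dl
                    improved = True
        if dl < best_dl - 1e-12:
            best_dl = dl
            best_labels = state.labels.copy()

    assert best_labels is not None
    # canonical labelling: blocks renumbered by order of first appearance
    remap: dict[int, int] = {}
    for lbl in best_labels:
        remap.setdefault(int(lbl), len(remap))
    return {v: remap[int(b)] for v, b in zip(nodes, best_labels)}, float(best_dl)


# ---------------------------------------------------------------------------
# Subgraphs and components


def percentile_subgraph(graph: nx.Graph, q: float = 0.95) -> nx.Graph:
    """Subgraph of edges whose weight strictly exceeds the q-th percentile
    (linear interpolation) of all edge weights; isolated vertices dropped."""
    if not 0.0 < q < 1.0:
        raise ParameterError("q must lie in (0, 1)")
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)])
    if weights.size == 0:
        raise ParameterError("graph has no edges")
    threshold = float(np.quantile(weights, q))
    sub = nx.Graph()
    for u, v, d in graph.edges(data=True):
        if d["weight"] > threshold:
            sub.add_edge(u, v, **d)
    sub.graph["threshold"] = threshold
    return sub


@dataclass
class ComponentSet:
    """Connected components above a size floor, deterministically ordered."""

    components: list[set]
    min_vertices: int

    def __len__(self) -> int:
        return len(self.components)


def connected_components(graph: nx.Graph, min_vertices: int = 3) -> ComponentSet:
    """Components with at least ``min_vertices`` vertices, ordered by
    decreasing size then lexicographically smallest member."""
    comps = [set(c) for c in nx.connected_components(graph) if len(c) >= min_vertices]
    comps.sort(key=lambda c: (-len(c), min(map(str, c))))
    return ComponentSet(comps, min_vertices)


def write_graphml(graph: nx.Graph, block_of: dict | None, path) -> None:
    g = graph.copy()
    if block_of is not None:
        nx.set_node_attributes(g, {v: int(b) for v, b in block_of.items()}, "block")
    nx.write_graphml(g, path)
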