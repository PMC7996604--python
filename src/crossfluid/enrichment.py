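"""Hypergeometric overrepresentation analysis against GMT pathway collections."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from crossfluid.errors import ParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    members: frozenset


@dataclass
class PathwayCollection:
    pathways: list[Pathway]

    @property
    def universe(self) -> set:
        u: set = set()
        for p in self.pathways:
            u |= p.members
        return u


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int          # query members found in the pathway
    n: int          # query size within the universe
    K: int          # pathway size within the universe ("entities total")
    N: int          # universe size
    p: float
    fdr: float
    found_members: list


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file: id <TAB> description <TAB> member...

    Lines with fewer than three fields are rejected with a logged warning
    carrying the line number; duplicate members within a line are dropped
    with a warning.
    """
    pathways: list[Pathway] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("GMT line %d rejected: fewer than 3 fields", lineno)
                continue
            pid, name, *members = fields
            members = [m for m in members if m]
            if not members:
                log.warning("GMT line %d rejected: empty member list", lineno)
                continue
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.warning("GMT line %d: duplicate member IDs deduplicated", lineno)
            pathways.append(Pathway(pid, name, frozenset(unique)))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in collection.pathways:
            fh.write("\t".join([p.id, p.name, *sorted(p.members)]) + "\n")


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ParameterError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich(
    query,
    collection: PathwayCollection,
    min_found: int = 1,
    universe: set | None = None,
) -> list[EnrichmentResult]:
    """Overrepresentation of a query ID set in each pathway of a collection.

    The universe defaults to all compounds of the collection; query IDs
    outside the universe are dropped with a warning.  BH-FDR is computed
    across every tested pathway before the ``min_found`` filter, and results
    are sorted by (fdr, p, id).
    """
    uni = set(universe) if universe is not None else collection.universe
    query = set(query)
    dropped = query - uni
    if dropped:
        log.warning("%d query IDs outside the universe dropped", len(dropped))
    q = query & uni
    if not q:
        log.warning("empty harmonized query; no enrichment computed")
        return []

    N = len(uni)
    n = len(q)
    raw: list[EnrichmentResult] = []
    for p in collection.pathways:
        members = p.members & uni
        K = len(members)
        found = sorted(q & members)
        k = len(found)
        pv = hypergeom_tail(k, n, K, N) if K > 0 else 1.0
        raw.append(EnrichmentResult(p.id, p.name, k, n, K, N, pv, np.nan, found))

    fdrs = bh_fdr([r.p for r in raw])
    for r, f in zip(raw, fdrs):
        r.fdr = float(f)
    kept = [r for r in raw if r.k >= min_found]
    kept.sort(key=lambda r: (r.fdr, r.p, r.pathway_id))
    return kept


def load_id_mapping(path) -> dict:
    """Two-column delimited file mapping metabolite name -> compound ID."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise ParameterError("mapping file needs two columns: name, compound_id")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
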