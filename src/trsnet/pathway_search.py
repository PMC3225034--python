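"""Top-scoring signaling path enumeration between start and end proteins.

A TRS pathway is a simple directed path from a start protein (ligand or
transmembrane receptor) to an end protein (transcription factor or known
terminal), at most ``max_len`` edges long, scored by ``P(N, E) =
T(N) + R(E)`` (see :mod:`trsnet.scoring`).  The background correction inside
P depends on path length, so no additive edge weight reproduces it exactly.
Candidate paths are therefore generated with a non-negative additive
surrogate weight

    w(u -> v) = (z_max - z_v) + (1 - r_uv)

(``z_max`` the largest deviate in the network, ``r_uv`` the edge
reliability, 1 for protein-DNA edges) by best-first enumeration of simple
paths in increasing surrogate cost, stratified by path length with a quota
of ``top_k * overgen`` candidates per (end, length) stratum, and the
candidates are then rescored exactly with P.  On small graphs the
enumeration is effectively exhaustive; the brute-force oracle in the test
suite bounds the risk of missing true top paths.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, replace

import numpy as np

from . import scoring
from .network_model import PD, PPI, Expr, OmicsNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TRSPathway:
    """A scored simple path from a start to an end protein.

    ``expression_score`` is the aggregate-only corrected score S(N), the
    alternative ranking key; ``T`` additionally counts the raw terminal
    deviates, and ``P = T + R``.
    """

    nodes: tuple
    edges: tuple                      # ((u, v, kind), ...)
    T: float
    R: float
    P: float
    expression_score: float
    p_value: float | None = None

    @property
    def start(self) -> str:
        return self.nodes[0]

    @property
    def end(self) -> str:
        return self.nodes[-1]

    def with_pvalue(self, p: float) -> "TRSPathway":
        return replace(self, p_value=p)


# ---------------------------------------------------------------------------
# adjacency extraction


def _adjacency(net: OmicsNetwork, expr: dict) -> dict:
    """node -> sorted list of (target, kind, reliability, surrogate weight).

    Parallel PPI and PD edges between the same ordered pair collapse to one
    representative edge, PPI preferred (it carries the reliability term).
    """
    z_max = max((e.z for e in expr.values()), default=0.0)
    chosen: dict[str, dict[str, tuple]] = {}
    for u, v, kind, data in net.edges():
        slot = chosen.setdefault(u, {})
        if v in slot and slot[v][0] == PPI:
            continue
        if kind == PPI:
            r = data.get("reliability")
            r = 1.0 if r is None else float(r)
        else:
            r = 1.0
        slot[v] = (kind, r)
    adj: dict[str, list] = {}
    for u, targets in chosen.items():
        row = []
        for v in sorted(targets):
            kind, r = targets[v]
            w = (z_max - expr[v].z) + (1.0 - r)
            row.append((v, kind, r, max(w, 0.0)))
        adj[u] = row
    return adj


def _collect_candidates(adj: dict, start: str, ends: frozenset, max_len: int,
                        quota: int, max_pops: int) -> dict:
    """Best-first enumeration of simple paths from ``start`` to any end.

    Returns end -> list of node tuples, collected in increasing surrogate
    cost with at most ``quota`` paths per (end, length) stratum.  The search
    stops when every stratum is full, the heap drains, or ``max_pops``
    labels have been expanded (determinism is unaffected: labels are popped
    in (cost, path) order).
    """
    found: dict[str, list] = {e: [] for e in ends}
    stratum: dict[tuple, int] = {}
    remaining = len(ends) * max_len
    heap = [(0.0, (start,))]
    pops = 0
    while heap and remaining > 0 and pops < max_pops:
        cost, path = heapq.heappop(heap)
        pops += 1
        node = path[-1]
        plen = len(path) - 1
        if node in ends and plen >= 1:
            key = (node, plen)
            c = stratum.get(key, 0)
            if c < quota:
                stratum[key] = c + 1
                found[node].append(path)
                if c + 1 == quota:
                    remaining -= 1
        if plen >= max_len:
            continue
        seen = set(path)
        for v, _, _, w in adj.get(node, ()):
            if v not in seen:
                heapq.heappush(heap, (cost + w, path + (v,)))
    return found


# ---------------------------------------------------------------------------
# exact scoring


def _score_nodes(nodes, adj: dict, expr: dict, bg_nodes, bg_edges) -> TRSPathway:
    zs = [expr[n].z for n in nodes]
    s = scoring.corrected_score(scoring.aggregate_z(zs), len(zs), bg_nodes)
    T = s + zs[0] + zs[-1]
    edges = []
    rels = []
    for u, v in zip(nodes[:-1], nodes[1:]):
        for t, kind, r, _ in adj[u]:
            if t == v:
                edges.append((u, v, kind))
                if kind == PPI:
                    rels.append(r)
                break
        else:  # pragma: no cover - candidates come from the same adjacency
            raise KeyError(f"no edge {u}->{v}")
    R = scoring.path_reliability_score(rels, bg_edges)
    return TRSPathway(nodes=tuple(nodes), edges=tuple(edges), T=T, R=R,
                      P=T + R, expression_score=s)


def score_path(net: OmicsNetwork, nodes, bg_nodes, bg_edges,
               expr: dict | None = None) -> TRSPathway:
    """Score an explicit node chain with the full pathway score P(N, E)."""
    expr = expr if expr is not None else net.expression_view()
    return _score_nodes(tuple(nodes), _adjacency(net, expr), expr,
                        bg_nodes, bg_edges)


# ---------------------------------------------------------------------------
# public search


def find_trs_pathways(net: OmicsNetwork, bg_nodes, bg_edges, start=None,
                      end=None, max_len: int = 10, top_k: int = 5,
                      overgen: int = 20, max_pops: int = 200_000,
                      expr: dict | None = None) -> list[TRSPathway]:
    """Up to ``top_k`` top-P simple paths per (start, end) pair.

    ``start``/``end`` may name single genes (which must carry the matching
    role) or be None, meaning all start-role / end-role genes; in all-pairs
    mode the per-pair top_k is enforced before pooling.  The pooled result
    is sorted by P descending with a lexicographic node-sequence tie-break.
    The network must already be localization- and reliability-filtered with
    expression attached; ``expr`` overrides the stored expression view
    (used by the permutation tests).
    """
    expr = expr if expr is not None else net.expression_view()

    def role_set(gene, role, fallback):
        if gene is None:
            return fallback
        if gene not in net:
            raise KeyError(f"{role} gene {gene!r} not in network")
        if role not in net.roles_of(gene):
            raise ValueError(f"gene {gene!r} does not carry the {role} role")
        return [gene]

    starts = role_set(start, "start", net.start_genes())
    ends = frozenset(role_set(end, "end", net.end_genes()))
    if not starts or not ends:
        raise ValueError("network has no start or no end genes")

    adj = _adjacency(net, expr)
    quota = max(1, top_k * overgen)
    results: list[TRSPathway] = []
    for s in starts:
        reachable = _collect_candidates(adj, s, ends - {s}, max_len, quota,
                                        max_pops)
        for e in sorted(reachable):
            scored = [_score_nodes(p, adj, expr, bg_nodes, bg_edges)
                      for p in reachable[e]]
            scored.sort(key=lambda pw: (-pw.P, pw.nodes))
            results.extend(scored[:top_k])
    results.sort(key=lambda pw: (-pw.P, pw.nodes))
    return results


def rank_pathways(paths, by: str = "path_score") -> list[TRSPathway]:
    """Stable descending sort by path score P or expression score S(N)."""
    if by == "path_score":
        key = lambda pw: (-pw.P, pw.nodes)
    elif by == "expression_score":
        key = lambda pw: (-pw.expression_score, pw.nodes)
    else:
        raise ValueError("by must be 'path_score' or 'expression_score'")
    return sorted(paths, key=key)


# ---------------------------------------------------------------------------
# permutation significance


def permute_expression(expr: dict, rng: np.random.Generator) -> dict:
    """Randomly reassign the (z, p, logFC, is_deg) tuples across genes."""
    genes = sorted(expr)
    perm = rng.permutation(len(genes))
    return {g: expr[genes[perm[i]]] for i, g in enumerate(genes)}


def pathway_pvalue(path: TRSPathway, net: OmicsNetwork, bg_nodes, bg_edges,
                   n_perm: int = 1000, seed: int | None = None,
                   max_len: int = 10, overgen: int = 20,
                   max_pops: int = 200_000) -> float:
    """Permutation p-value of a pathway's score.

    Expression tuples are permuted across all network genes (edge
    reliabilities stay fixed) and the search between the same start and end
    is rerun; p = (1 + #{permutation best >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        logger.warning("pathway_pvalue: n_perm=%d is small; the p-value "
                       "resolution is only %.3g", n_perm, 1.0 / (n_perm + 1))
    rng = np.random.default_rng(seed)
    expr = net.expression_view()
    exceed = 0
    for _ in range(n_perm):
        permuted = permute_expression(expr, rng)
        best = find_trs_pathways(net, bg_nodes, bg_edges, start=path.start,
                                 end=path.end, max_len=max_len, top_k=1,
                                 overgen=overgen, max_pops=max_pops,
                                 expr=permuted)
        if best and best[0].P >= path.P:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)
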