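"""Growth of a TRS network from a seed pathway via TF -> target edges.

A TRS network captures transcription-mediated cross-talk: the seed pathway
delivers a signal to its terminal transcription factor, whose outgoing
edges (protein-DNA edges to induced targets, or edges back into the
network) are followed.  A target that is itself a start protein,
differentially expressed and positively regulated pulls its own significant
top pathways into the network, and those pathways' end nodes continue the
expansion.  The procedure is a FIFO queue over end nodes with each node
processed at most once, so it terminates on every finite graph.

Growth (queue semantics, pull caps, DEG gates) lives in
:func:`grow_trs_network`; the composite score ``SF = (S + sum P_i) / |E|``
in :func:`score_trs_network`; permutation significance, which reruns the
whole pathway search and growth under permuted expression, in
:func:`network_pvalue`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import scoring
from .network_model import OmicsNetwork
from .pathway_search import (TRSPathway, find_trs_pathways,
                             permute_expression, score_path)

logger = logging.getLogger(__name__)


@dataclass
class TRSNetwork:
    """A grown subnetwork with its member pathways and score components."""

    nodes: set
    edges: set                               # {(u, v, kind), ...}
    member_pathways: list
    seed_gene: str
    S: float | None = None
    P_sum: float | None = None
    SF: float | None = None
    p_value: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SearchConfig:
    """Everything needed to replay the pathway search + growth end to end."""

    pairs: list | None = None                # [(start, end), ...] or None = all roles
    start_gene: str | None = None
    top_k: int = 5
    max_len: int = 10
    overgen: int = 20
    max_pops: int = 200_000
    significance_cutoff: float = 0.05
    max_pathways_per_start: int = 3


def _eligible_by_start(pathways, cutoff: float, cap: int) -> dict:
    """start gene -> top pathways passing the significance cutoff.

    Pathways without a computed p-value pass (permutation reruns cannot
    recompute nested p-values).  Ranked by P descending, capped at ``cap``.
    """
    by_start: dict[str, list] = {}
    for pw in pathways:
        if pw.p_value is not None and pw.p_value > cutoff:
            continue
        by_start.setdefault(pw.start, []).append(pw)
    for s in by_start:
        by_start[s].sort(key=lambda pw: (-pw.P, pw.nodes))
        by_start[s] = by_start[s][:cap]
    return by_start


def grow_trs_network(net: OmicsNetwork, pathways, start_gene: str | None = None,
                     significance_cutoff: float = 0.05,
                     max_pathways_per_start: int = 3,
                     expr: dict | None = None) -> TRSNetwork:
    """Queue-based expansion of a seed pathway into a TRS network.

    Seeded with the top-ranked pathway of ``start_gene`` (or of the globally
    highest-scoring pathway when unset).  End nodes are polled FIFO; for
    each outgoing edge of a polled node, the target is added (with the edge)
    when it is a DEG or already in the network.  An added target that is a
    start protein, a DEG and positively regulated (log fold change > 0)
    pulls in its top-ranked significant pathways and enqueues their end
    nodes; an added target that is an end protein and a DEG is enqueued.
    Each node is enqueued at most once.
    """
    if not pathways:
        raise ValueError("grow_trs_network: empty pathway list")
    expr = expr if expr is not None else net.expression_view()
    by_start = _eligible_by_start(pathways, significance_cutoff,
                                  max_pathways_per_start)

    if start_gene is not None:
        candidates = by_start.get(start_gene)
        if not candidates:
            raise ValueError(f"no admissible pathway starts at {start_gene!r}")
        seed = candidates[0]
    else:
        seed = min((pw for lst in by_start.values() for pw in lst),
                   key=lambda pw: (-pw.P, pw.nodes), default=None)
        if seed is None:
            raise ValueError("no pathway passes the significance cutoff")

    g = TRSNetwork(nodes=set(seed.nodes), edges=set(seed.edges),
                   member_pathways=[seed], seed_gene=seed.start)
    member_keys = {seed.nodes}
    queue: deque[str] = deque([seed.end])
    enqueued = {seed.end}
    pulled = {seed.start}

    def pull(t: str) -> None:
        for pw in by_start.get(t, []):
            g.nodes.update(pw.nodes)
            g.edges.update(pw.edges)
            if pw.nodes not in member_keys:
                member_keys.add(pw.nodes)
                g.member_pathways.append(pw)
            if pw.end not in enqueued:
                enqueued.add(pw.end)
                queue.append(pw.end)

    while queue:
        e = queue.popleft()
        out_edges = sorted((v, kind) for _, v, kind, _ in net.graph.out_edges(
            e, keys=True, data=True))
        for t, kind in out_edges:
            if not (expr[t].is_deg or t in g.nodes):
                continue
            g.nodes.add(t)
            g.edges.add((e, t, kind))
            roles = net.roles_of(t)
            if ("start" in roles and expr[t].is_deg
                    and expr[t].log_fold_change > 0 and t not in pulled):
                pulled.add(t)
                pull(t)
            if "end" in roles and expr[t].is_deg and t not in enqueued:
                enqueued.add(t)
                queue.append(t)
    return g


def score_trs_network(g: TRSNetwork, net: OmicsNetwork, bg_nodes,
                      expr: dict | None = None) -> TRSNetwork:
    """Fill in S, sum of member pathway scores, and SF = (S + sum P) / |E|.

    Nodes and edges belonging to no member pathway (the interconnecting
    material) contribute to S and to the edge count only.
    """
    if not g.nodes:
        raise ValueError("cannot score an empty network")
    expr = expr if expr is not None else net.expression_view()
    zs = [expr[n].z for n in sorted(g.nodes)]
    g.S = scoring.corrected_score(scoring.aggregate_z(zs), len(zs), bg_nodes)
    g.P_sum = float(sum(pw.P for pw in g.member_pathways))
    g.SF = scoring.network_score(g.S, [g.P_sum], g.n_edges)
    return g


def run_trs_search(net: OmicsNetwork, bg_nodes, bg_edges, cfg: SearchConfig,
                   expr: dict | None = None) -> TRSNetwork:
    """Pathway search + growth + scoring under one configuration.

    The single entry point replayed per permutation by
    :func:`network_pvalue` in full mode.
    """
    expr = expr if expr is not None else net.expression_view()
    if cfg.pairs is None:
        pathways = find_trs_pathways(net, bg_nodes, bg_edges, max_len=cfg.max_len,
                                     top_k=cfg.top_k, overgen=cfg.overgen,
                                     max_pops=cfg.max_pops, expr=expr)
    else:
        pathways = []
        for s, e in cfg.pairs:
            pathways.extend(find_trs_pathways(
                net, bg_nodes, bg_edges, start=s, end=e, max_len=cfg.max_len,
                top_k=cfg.top_k, overgen=cfg.overgen, max_pops=cfg.max_pops,
                expr=expr))
    if not pathways:
        raise ValueError("no admissible pathway under this configuration")
    g = grow_trs_network(net, pathways, start_gene=cfg.start_gene,
                         significance_cutoff=cfg.significance_cutoff,
                         max_pathways_per_start=cfg.max_pathways_per_start,
                         expr=expr)
    return score_trs_network(g, net, bg_nodes, expr=expr)


def rescore_network(g: TRSNetwork, net: OmicsNetwork, bg_nodes, bg_edges,
                    expr: dict) -> float:
    """SF of the observed topology under a different expression assignment."""
    zs = [expr[n].z for n in sorted(g.nodes)]
    S = scoring.corrected_score(scoring.aggregate_z(zs), len(zs), bg_nodes)
    p_sum = sum(score_path(net, pw.nodes, bg_nodes, bg_edges, expr=expr).P
                for pw in g.member_pathways)
    return scoring.network_score(S, [p_sum], g.n_edges)


def network_pvalue(g: TRSNetwork, net: OmicsNetwork, bg_nodes, bg_edges,
                   cfg: SearchConfig, n_perm: int = 1000,
                   seed: int | None = None, mode: str = "full") -> float:
    """Permutation p-value of a TRS network's composite score SF.

    ``mode="full"`` reruns the entire pathway search and growth per
    permutation (the literal procedure); ``mode="fast"`` keeps the observed
    topology and only rescores it under permuted expression.
    """
    if n_perm < 100:
        logger.warning("network_pvalue: n_perm=%d gives coarse resolution", n_perm)
    if mode not in ("full", "fast"):
        raise ValueError("mode must be 'full' or 'fast'")
    rng = np.random.default_rng(seed)
    expr = net.expression_view()
    exceed = 0
    for _ in range(n_perm):
        permuted = permute_expression(expr, rng)
        if mode == "full":
            try:
                sf = run_trs_search(net, bg_nodes, bg_edges, cfg,
                                    expr=permuted).SF
            except ValueError:
                sf = -np.inf
        else:
            sf = rescore_network(g, net, bg_nodes, bg_edges, permuted)
        if sf >= g.SF:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)
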