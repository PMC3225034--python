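"""Baseline subnetworks, overlap significance, and kinase annotation."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .network_model import OmicsNetwork, PPI
from .network_search import TRSNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """One-sided Fisher exact enrichment of a subnetwork in a reference set."""

    level: str                       # "node" or "edge"
    a: int                           # in sub and in reference
    b: int                           # in sub only
    c: int                           # in reference only
    d: int                           # in neither
    p_value: float
    neg_log_p: float


def build_d2d_network(net: OmicsNetwork, degs) -> TRSNetwork:
    """DEG-to-DEG baseline: DEGs linked by their direct PPIs.

    Nodes are the DEGs present in the network; edges are exactly the PPI
    edges of ``net`` with both endpoints differentially expressed.
    """
    degs = set(degs)
    present = degs & set(net.nodes())
    if len(present) < len(degs):
        logger.info("build_d2d_network: %d DEG ids absent from network",
                    len(degs) - len(present))
    edges = {(u, v, k) for u, v, k, _ in net.edges(kind=PPI)
             if u in present and v in present}
    return TRSNetwork(nodes=present, edges=edges, member_pathways=[],
                      seed_gene="")


def overlap_significance(sub, reference, universe, level: str = "node",
                         undirected_edges: bool = False) -> OverlapResult:
    """Hypergeometric upper-tail (one-sided Fisher exact) overlap test.

    ``sub``, ``reference`` and ``universe`` are item sets — gene ids at the
    node level, (source, target, kind) triples at the edge level.  With
    ``undirected_edges`` edge triples match regardless of direction, for
    reference pathways that carry none.
    """
    def norm(items):
        out = set(items)
        if level == "edge" and undirected_edges:
            out = {(min(u, v), max(u, v), k) for u, v, k in out}
        return out

    uni = norm(universe)
    if not uni:
        raise ValueError("empty universe")
    s = norm(sub) & uni
    r = norm(reference) & uni
    a = len(s & r)
    b = len(s - r)
    c = len(r - s)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    p = float(p)
    return OverlapResult(level=level, a=a, b=b, c=c, d=d, p_value=p,
                         neg_log_p=-math.log(p))


def annotate_kinase_reactions(net: OmicsNetwork, pairs) -> OmicsNetwork:
    """Flag network edges matching known (kinase, substrate) pairs.

    Phosphorylation drives most signal relays, so matched edges gain
    ``kinase_reaction = True``.  Pairs without a matching edge are no-ops.
    Returns a new network.
    """
    out = net.copy()
    pair_set = {(str(k), str(s)) for k, s in pairs}
    n = 0
    for u, v, kind, data in out.edges():
        if (u, v) in pair_set:
            data["kinase_reaction"] = True
            n += 1
    logger.info("annotate_kinase_reactions: annotated %d edges", n)
    return out
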