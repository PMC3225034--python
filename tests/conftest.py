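"""Shared builders for hand-crafted networks and the traceable growth toy."""

from __future__ import annotations

import numpy as np
import pytest

from trsnet import BackgroundTable, OmicsNetwork, build_background
from trsnet.network_model import PD, PPI
from trsnet.pathway_search import TRSPathway


def make_net(ppi=(), pd=(), starts=(), ends=(), locs=None, z=None, deg=None,
             lfc=None):
    """Build an OmicsNetwork directly with explicit attributes.

    ``ppi`` is a list of (u, v[, reliability]) *directed* edges; ``pd`` of
    (u, v) directed edges.  ``locs``/``z``/``deg``/``lfc`` are per-gene
    mappings; omitted genes get unconstrained localization and null
    expression.
    """
    net = OmicsNetwork()
    locs, z, deg, lfc = locs or {}, z or {}, deg or {}, lfc or {}

    def ensure(g):
        net.add_gene(g)
        node = net.node(g)
        node["localizations"] = frozenset(locs.get(g, ()))
        node["z_score"] = float(z.get(g, 0.0))
        node["is_deg"] = bool(deg.get(g, False))
        node["log_fold_change"] = float(lfc.get(g, z.get(g, 0.0)))
        roles = set()
        if g in starts:
            roles.add("start")
        if g in ends:
            roles.add("end")
        node["roles"] = frozenset(roles)

    for rec in ppi:
        u, v = rec[0], rec[1]
        r = float(rec[2]) if len(rec) > 2 else 0.9
        ensure(u), ensure(v)
        net.graph.add_edge(u, v, key=PPI, kind=PPI, provenance={"test"},
                           paper_count=0, reliability=r)
    for u, v in pd:
        ensure(u), ensure(v)
        net.graph.add_edge(u, v, key=PD, kind=PD, provenance={"test"},
                           paper_count=0, reliability=None, pd_sign="unknown")
    for g in set(starts) | set(ends):
        if g not in net:
            ensure(g)
    return net


def flat_background(k_max: int, kind: str = "node_z") -> BackgroundTable:
    """A mu=0 / sigma=1 table, so corrected scores equal raw aggregates."""
    sizes = np.arange(1, k_max + 1)
    one = np.ones(k_max)
    return BackgroundTable(kind=kind, sizes=sizes, mu=np.zeros(k_max),
                           sigma=one, mu_s=np.zeros(k_max), sigma_s=one,
                           n_samples=0, window=1)


@pytest.fixture(scope="session")
def bg_pools():
    """Standard-normal node pool and uniform(0.6, 1) reliability pool tables."""
    rng = np.random.default_rng(20240917)
    bg_nodes = build_background(rng.standard_normal(400), k_max=13,
                                n_samples=4000, window=5, seed=11)
    bg_edges = build_background(rng.uniform(0.6, 1.0, 400), k_max=12,
                                n_samples=4000, window=5, seed=12)
    return bg_nodes, bg_edges


def growth_toy():
    """Hand-traceable 7-node growth instance.

    Seed pathway A->B->C (start A, TF C).  C regulates D (a start protein,
    DEG, induced) whose pathway D->E->F is pulled in, and G (a plain DEG
    target).  Expected network: both pathways plus the two PD edges out of
    C; manual execution of the queue algorithm gives exactly
    nodes {A..G} and edges {A->B, B->C, C->D, C->G, D->E, E->F}.
    """
    net = make_net(
        ppi=[("A", "B", 0.9), ("B", "C", 0.9), ("D", "E", 0.9), ("E", "F", 0.9)],
        pd=[("C", "D"), ("C", "G")],
        starts={"A", "D"}, ends={"C", "F"},
        deg={"C": True, "D": True, "F": True, "G": True},
        lfc={"C": 1.0, "D": 2.0, "F": 1.5, "G": 0.5},
        z={"C": 2.0, "D": 2.5, "F": 2.2, "G": 2.1},
    )
    seed_pw = TRSPathway(nodes=("A", "B", "C"),
                         edges=(("A", "B", PPI), ("B", "C", PPI)),
                         T=6.0, R=1.0, P=7.0, expression_score=4.0,
                         p_value=0.001)
    second_pw = TRSPathway(nodes=("D", "E", "F"),
                           edges=(("D", "E", PPI), ("E", "F", PPI)),
                           T=5.0, R=0.8, P=5.8, expression_score=3.5,
                           p_value=0.002)
    expected_nodes = set("ABCDEFG")
    expected_edges = {("A", "B", PPI), ("B", "C", PPI), ("C", "D", PD),
                      ("C", "G", PD), ("D", "E", PPI), ("E", "F", PPI)}
    return net, [seed_pw, second_pw], expected_nodes, expected_edges
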