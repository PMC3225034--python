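"""Directed omics network of protein-protein and protein-DNA interactions.

The network integrates two edge types:

* **PPI** — physical protein-protein interactions.  Source databases report
  these without direction, so every undirected pair is expanded into two
  opposite directed edges before any filtering.  Curated signaling resources
  (KEGG-style) may contribute *directed* PPIs, which are kept as given and do
  not spawn a reverse edge.
* **PD** — protein-DNA interactions, i.e. transcription-factor -> target
  edges.  These are directed by nature and act at the nucleus.

Nodes carry subcellular localization (extracellular, plasma membrane,
cytoplasm, nucleus, other), start/end roles for the path search (ligand or
transmembrane proteins start a signal; transcription factors or proteins with
a clearly known terminal role end it), and differential-expression
annotation: a p-value, a log fold change, the derived normal deviate
``z = inverse_normal_cdf(1 - p)`` and a DEG flag (``p < deg_cutoff``).

Signals flow from the extracellular space toward the nucleus, so
:func:`localization_filter` removes PPI edges that run against the
extracellular -> plasma membrane -> cytoplasm -> nucleus order.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .scoring import z_from_p

logger = logging.getLogger(__name__)

PPI = "PPI"
PD = "PD"

#: Rank of each compartment along the direction of signal flow.
LOCALIZATION_RANK = {
    "extracellular": 0,
    "plasma_membrane": 1,
    "cytoplasm": 2,
    "nucleus": 3,
}

#: Per-gene expression view used throughout the search modules.
Expr = namedtuple("Expr", ["z", "p", "log_fold_change", "is_deg"])

_NODE_DEFAULTS = {
    "localizations": frozenset(),
    "roles": frozenset(),
    "p_value": None,
    "log_fold_change": 0.0,
    "z_score": 0.0,
    "is_deg": False,
}


class OmicsNetwork:
    """Directed multigraph of typed gene-gene interactions.

    A thin wrapper over :class:`networkx.MultiDiGraph` keyed by edge kind
    (``"PPI"`` / ``"PD"``), so at most one edge exists per
    (source, target, kind) triple.
    """

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.graph = graph if graph is not None else nx.MultiDiGraph()

    # -- container basics -------------------------------------------------
    def copy(self) -> "OmicsNetwork":
        return OmicsNetwork(self.graph.copy())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.graph

    def nodes(self):
        return self.graph.nodes()

    def node(self, gene_id: str) -> dict:
        return self.graph.nodes[gene_id]

    def add_gene(self, gene_id: str) -> None:
        if gene_id not in self.graph:
            self.graph.add_node(gene_id, **dict(_NODE_DEFAULTS))

    def edges(self, kind: str | None = None):
        """Yield (source, target, kind, data) for all (or one kind of) edges."""
        for u, v, k, data in self.graph.edges(keys=True, data=True):
            if kind is None or k == kind:
                yield u, v, k, data

    def has_edge(self, u: str, v: str, kind: str) -> bool:
        return self.graph.has_edge(u, v, key=kind)

    def edge(self, u: str, v: str, kind: str) -> dict:
        return self.graph.edges[u, v, kind]

    # -- derived views -----------------------------------------------------
    def roles_of(self, gene_id: str) -> frozenset:
        return self.graph.nodes[gene_id].get("roles", frozenset())

    def start_genes(self) -> list[str]:
        return sorted(n for n in self.graph if "start" in self.roles_of(n))

    def end_genes(self) -> list[str]:
        return sorted(n for n in self.graph if "end" in self.roles_of(n))

    def expression_view(self) -> dict[str, Expr]:
        """Snapshot gene -> (z, p, logFC, is_deg), the permutable quantity."""
        view = {}
        for n, d in self.graph.nodes(data=True):
            view[n] = Expr(
                d.get("z_score", 0.0),
                d.get("p_value"),
                d.get("log_fold_change", 0.0),
                d.get("is_deg", False),
            )
        return view

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OmicsNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


# ---------------------------------------------------------------------------
# construction


def _edge_records(table, default_provenance: str, directed_kind: str):
    """Normalise an edge-list input into (source, target, provenance, count, sign).

    Accepts a pandas DataFrame with columns ``source``/``target`` (optional
    ``provenance``, ``paper_count``, ``pd_sign``) or any iterable of 2- to
    5-tuples.
    """
    if table is None:
        return
    if isinstance(table, pd.DataFrame):
        cols = table.columns
        for row in table.itertuples(index=False):
            d = dict(zip(cols, row))
            yield (
                str(d["source"]),
                str(d["target"]),
                str(d.get("provenance", default_provenance) or default_provenance),
                int(d.get("paper_count", 0) or 0),
                str(d.get("pd_sign", "unknown") or "unknown"),
            )
    else:
        for rec in table:
            rec = tuple(rec)
            u, v = str(rec[0]), str(rec[1])
            prov = str(rec[2]) if len(rec) > 2 and rec[2] else default_provenance
            count = int(rec[3]) if len(rec) > 3 and rec[3] else 0
            sign = str(rec[4]) if len(rec) > 4 and rec[4] else "unknown"
            yield u, v, prov, count, sign


def _merge_edge(store: dict, u: str, v: str, kind: str, prov: str, count: int,
                sign: str) -> None:
    key = (u, v, kind)
    if key not in store:
        store[key] = {
            "provenance": set(),
            "paper_count": 0,
            "pd_sign": sign if kind == PD else None,
            "reliability": None,
        }
    entry = store[key]
    if prov not in entry["provenance"]:
        entry["provenance"].add(prov)
        entry["paper_count"] += count
    if kind == PD and sign != "unknown":
        if entry["pd_sign"] in (None, "unknown"):
            entry["pd_sign"] = sign
        elif entry["pd_sign"] != sign:
            logger.warning("conflicting PD sign for %s->%s; set to unknown", u, v)
            entry["pd_sign"] = "unknown"


def build_network(
    ppi_edges=None,
    pd_edges=None,
    kegg_ppi=None,
    kegg_pd=None,
    alias_map: Mapping[str, str] | None = None,
) -> OmicsNetwork:
    """Assemble the directed omics network from raw edge lists.

    ``ppi_edges`` are undirected pairs: each is expanded into two opposite
    directed PPI edges.  ``kegg_ppi`` pairs are already directed and kept as
    given.  ``pd_edges``/``kegg_pd`` are directed TF -> target edges.
    Duplicate (source, target, kind) triples across sources are merged:
    provenance tags are unioned and per-source paper counts summed once per
    tag.  ``alias_map``, when given, canonicalises identifiers; ids missing
    from the map are skipped with a logged count.
    """
    store: dict = {}
    skipped = 0

    def resolve(g: str) -> str | None:
        if alias_map is None:
            return g
        return alias_map.get(g, g if g in alias_map.values() else None)

    def ingest(table, kind: str, undirected: bool, default_prov: str):
        nonlocal skipped
        for u, v, prov, count, sign in _edge_records(table, default_prov, kind):
            ru, rv = resolve(u), resolve(v)
            if ru is None or rv is None:
                skipped += 1
                continue
            _merge_edge(store, ru, rv, kind, prov, count, sign)
            if undirected and ru != rv:
                _merge_edge(store, rv, ru, kind, prov, count, sign)

    ingest(ppi_edges, PPI, undirected=True, default_prov="ppi")
    ingest(pd_edges, PD, undirected=False, default_prov="pd")
    ingest(kegg_ppi, PPI, undirected=False, default_prov="kegg")
    ingest(kegg_pd, PD, undirected=False, default_prov="kegg")

    if skipped:
        logger.warning("build_network: skipped %d edges with unresolvable ids", skipped)

    net = OmicsNetwork()
    for (u, v, kind), data in store.items():
        net.add_gene(u)
        net.add_gene(v)
        attrs = dict(data)
        if kind != PD:
            attrs.pop("pd_sign")
        net.graph.add_edge(u, v, key=kind, kind=kind, **attrs)
    return net


def assign_roles(net: OmicsNetwork, start_ids: Iterable[str],
                 end_ids: Iterable[str]) -> OmicsNetwork:
    """Mark start (ligand/transmembrane) and end (TF/terminal) genes.

    A gene may hold both roles.  Ids absent from the network are logged and
    ignored; an empty start or end set is an error because the path search
    would be vacuous.
    """
    start_ids, end_ids = set(start_ids), set(end_ids)
    if not start_ids or not end_ids:
        raise ValueError("start and end gene sets must both be non-empty")
    out = net.copy()
    for role, ids in (("start", start_ids), ("end", end_ids)):
        missing = sorted(g for g in ids if g not in out)
        if missing:
            logger.info("assign_roles: %d %s ids absent from network (e.g. %s)",
                        len(missing), role, missing[:3])
        for g in ids - set(missing):
            node = out.node(g)
            node["roles"] = frozenset(node.get("roles", frozenset()) | {role})
    return out


def attach_localizations(net: OmicsNetwork, table) -> OmicsNetwork:
    """Attach subcellular localizations from a (gene_id, localization) table.

    ``table`` is a DataFrame with columns ``gene_id``/``localization`` or a
    mapping gene -> iterable of compartments.  Genes absent from the network
    are ignored.
    """
    out = net.copy()
    if isinstance(table, pd.DataFrame):
        grouped: dict[str, set] = {}
        for g, loc in zip(table["gene_id"].astype(str), table["localization"].astype(str)):
            grouped.setdefault(g, set()).add(loc)
    else:
        grouped = {str(g): set(locs) for g, locs in table.items()}
    for g, locs in grouped.items():
        if g in out:
            out.node(g)["localizations"] = frozenset(locs)
    return out


def localization_filter(net: OmicsNetwork) -> OmicsNetwork:
    """Drop PPI edges running against the extracellular -> nucleus order.

    An edge u -> v is kept iff *some* pair of localizations (l_u, l_v) is
    rank-non-decreasing, or either endpoint has no ranked localization
    (empty or "other"-only annotation is treated as unconstrained).  PD edges
    are never removed; transcription-factor -> target regulation acts at the
    nucleus regardless of where the product ends up.  Returns a new network.
    """
    out = net.copy()
    to_drop = []
    unknown = 0
    for u, v, kind, _ in out.edges(kind=PPI):
        ranks_u = [LOCALIZATION_RANK[l] for l in out.node(u).get("localizations", ())
                   if l in LOCALIZATION_RANK]
        ranks_v = [LOCALIZATION_RANK[l] for l in out.node(v).get("localizations", ())
                   if l in LOCALIZATION_RANK]
        if not ranks_u or not ranks_v:
            unknown += 1
            continue
        if min(ranks_u) > max(ranks_v):
            to_drop.append((u, v, kind))
    for u, v, kind in to_drop:
        out.graph.remove_edge(u, v, key=kind)
    logger.info("localization_filter: removed %d PPI edges (%d unconstrained kept)",
                len(to_drop), unknown)
    return out


def attach_expression(net: OmicsNetwork, table: pd.DataFrame,
                      deg_cutoff: float = 0.05) -> OmicsNetwork:
    """Attach differential-expression evidence to network genes.

    ``table`` needs columns ``gene_id``, ``p_value`` and ``log_fold_change``
    (``logFC`` accepted).  Matched genes get ``z = inverse_normal_cdf(1-p)``
    and ``is_deg = p < deg_cutoff``; unmeasured genes keep the neutral
    default z = 0, is_deg = False.
    """
    if not 0.0 <= deg_cutoff <= 1.0:
        raise ValueError(f"deg_cutoff must be in [0, 1], got {deg_cutoff}")
    out = net.copy()
    lfc_col = "log_fold_change" if "log_fold_change" in table.columns else "logFC"
    matched = 0
    for row in table.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        g = str(d["gene_id"])
        p = float(d["p_value"])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"gene {g}: p-value {p} outside [0, 1]")
        if g not in out:
            continue
        node = out.node(g)
        node["p_value"] = p
        node["log_fold_change"] = float(d[lfc_col])
        node["z_score"] = z_from_p(p)
        node["is_deg"] = p < deg_cutoff
        matched += 1
    logger.info("attach_expression: matched %d/%d genes, deg_cutoff=%g",
                matched, out.n_nodes, deg_cutoff)
    return out
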