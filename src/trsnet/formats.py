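"""Tabular and graph file formats shared across the toolkit.

Edge lists are header-full TSV (source, target, kind, provenance,
paper_count[, pd_sign]); SIF is accepted for PPI lists.  Localization is a
long-form (gene_id, localization) TSV, roles are one id per line,
expression is (gene_id, p_value, logFC) TSV, reference gene sets are GMT.
Networks export to GraphML with set-valued attributes joined by ``|``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .network_model import OmicsNetwork

logger = logging.getLogger(__name__)

_EDGE_COLUMNS = ("source", "target", "kind", "provenance", "paper_count", "pd_sign")


def read_edge_table(path) -> pd.DataFrame:
    """Read a TSV edge list, reporting malformed lines by number."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        unknown = [c for c in header if c not in _EDGE_COLUMNS]
        if "source" not in header or "target" not in header or unknown:
            raise ValueError(f"{path}:1: bad edge-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}")
            rec = dict(zip(header, fields))
            if "paper_count" in rec:
                try:
                    rec["paper_count"] = int(rec["paper_count"])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: paper_count {rec['paper_count']!r} "
                        "is not an integer") from None
            rows.append(rec)
    return pd.DataFrame(rows, columns=[c for c in header])


def read_sif(path) -> pd.DataFrame:
    """Read a SIF file into an undirected pair list (one row per pair)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: SIF line needs >= 3 fields")
            src = fields[0]
            for target in fields[2:]:
                rows.append({"source": src, "target": target})
    return pd.DataFrame(rows, columns=["source", "target"])


def read_localization(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "localization"} <= set(df.columns):
        raise ValueError(f"{path}: needs gene_id and localization columns")
    return df


def read_roles(path) -> list[str]:
    """One gene id per line."""
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["gene_id"] = df["gene_id"].astype(str)
    if "logFC" in df.columns and "log_fold_change" not in df.columns:
        df = df.rename(columns={"logFC": "log_fold_change"})
    if not {"gene_id", "p_value", "log_fold_change"} <= set(df.columns):
        raise ValueError(f"{path}: needs gene_id, p_value, logFC columns")
    return df


def read_gmt(path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
                continue
            sets[fields[0]] = set(fields[2:])
    return sets


def read_pairs(path) -> list[tuple[str, str]]:
    """Two-column TSV of (kinase, substrate) or (source, target) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    a, b = df.columns[:2]
    return list(zip(df[a], df[b]))


def read_reliability(path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    return {(min(u, v), max(u, v)): float(r)
            for u, v, r in zip(df["source"], df["target"],
                               df["mean_reliability"])}


def write_reliability(model, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tmean_reliability\tsd\n")
        for (u, v), r in sorted(model.mean_reliability.items()):
            sd = model.sd_reliability.get((u, v), 0.0)
            fh.write(f"{u}\t{v}\t{r:.6g}\t{sd:.6g}\n")


def write_pathways(paths, out) -> None:
    """Ranked pathway TSV: node chains are |-delimited."""
    from .scoring import format_pvalue  # local import avoids a cycle

    with open(out, "w") as fh:
        fh.write("rank\tstart\tend\tnode_chain\tT\tR\tP\texpression_score\tp_value\n")
        for i, pw in enumerate(paths, start=1):
            if pw.p_value is None:
                ptxt = "NA"
            else:
                ptxt = f"{pw.p_value:.6g}"
            fh.write(f"{i}\t{pw.start}\t{pw.end}\t{'|'.join(pw.nodes)}\t"
                     f"{pw.T:.6g}\t{pw.R:.6g}\t{pw.P:.6g}\t"
                     f"{pw.expression_score:.6g}\t{ptxt}\n")


def read_pathways(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


#: Fold-change bins used for node fill colors in network exports,
#: from strongly induced to strongly repressed.
LOGFC_BINS = [
    (3.0, float("inf"), "red"),
    (2.0, 3.0, "orange"),
    (1.0, 2.0, "yellow"),
    (0.5, 1.0, "light_yellow"),
    (-0.5, 0.5, "white"),
    (-1.0, -0.5, "light_cyan"),
    (-2.0, -1.0, "cyan"),
    (-3.0, -2.0, "navy_blue"),
    (float("-inf"), -3.0, "blue"),
]


def logfc_color(lfc: float) -> str:
    for lo, hi, color in LOGFC_BINS:
        if lo <= lfc < hi or (hi == float("inf") and lfc >= lo):
            return color
    return "white"


def export_graphml(net: OmicsNetwork, path) -> None:
    """GraphML export with scalarised node/edge attributes."""
    g = nx.MultiDiGraph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(
            n,
            z=float(d.get("z_score", 0.0)),
            p=-1.0 if d.get("p_value") is None else float(d["p_value"]),
            logFC=float(d.get("log_fold_change", 0.0)),
            is_deg=bool(d.get("is_deg", False)),
            roles="|".join(sorted(d.get("roles", ()))),
            localizations="|".join(sorted(d.get("localizations", ()))),
            fill=logfc_color(float(d.get("log_fold_change", 0.0))),
        )
    for u, v, k, d in net.graph.edges(keys=True, data=True):
        attrs = {
            "kind": d.get("kind", k),
            "provenance": "|".join(sorted(d.get("provenance", ()))),
            "paper_count": int(d.get("paper_count", 0)),
        }
        if d.get("reliability") is not None:
            attrs["reliability"] = float(d["reliability"])
        if d.get("pd_sign"):
            attrs["pd_sign"] = d["pd_sign"]
        if d.get("kinase_reaction"):
            attrs["kinase_reaction"] = True
        g.add_edge(u, v, key=k, **attrs)
    nx.write_graphml(g, path)


def import_graphml(path) -> OmicsNetwork:
    g = nx.read_graphml(path, force_multigraph=True)
    out = nx.MultiDiGraph()
    for n, d in g.nodes(data=True):
        p = d.get("p", -1.0)
        out.add_node(
            n,
            z_score=float(d.get("z", 0.0)),
            p_value=None if p is None or float(p) < 0 else float(p),
            log_fold_change=float(d.get("logFC", 0.0)),
            is_deg=bool(d.get("is_deg", False)),
            roles=frozenset(x for x in str(d.get("roles", "")).split("|") if x),
            localizations=frozenset(
                x for x in str(d.get("localizations", "")).split("|") if x),
        )
    for u, v, k, d in g.edges(keys=True, data=True):
        kind = d.get("kind", k)
        attrs = {
            "kind": kind,
            "provenance": set(x for x in str(d.get("provenance", "")).split("|") if x),
            "paper_count": int(d.get("paper_count", 0)),
            "reliability": float(d["reliability"]) if "reliability" in d else None,
        }
        if kind == "PD":
            attrs["pd_sign"] = d.get("pd_sign", "unknown")
        out.add_edge(u, v, key=kind, **attrs)
    return OmicsNetwork(out)
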