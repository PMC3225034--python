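"""End-to-end pipeline: build -> reliability -> backgrounds -> search -> growth.

A :class:`RunConfig` gathers every input path and tuning parameter (the
defaults mirror the method's fixed settings: DEG cutoff p < 0.05,
reliability floor 0.6, path length <= 10, 100,000 background samples,
1,000 permutations).  :func:`run_pipeline` executes the stages, writes the
result tables plus a provenance manifest, and aborts with the stage name on
any error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import formats, network_model as nm, scoring
from .network_search import SearchConfig, grow_trs_network, score_trs_network
from .pathway_search import find_trs_pathways, pathway_pvalue

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one discovery run; seed is mandatory."""

    ppi: str | None = None
    pd_edges: str | None = None
    kegg_ppi: str | None = None
    kegg_pd: str | None = None
    localization: str | None = None
    starts: str | None = None
    ends: str | None = None
    expression: str | None = None
    reliability: str | None = None          # precomputed per-pair TSV
    deg_cutoff: float = 0.05
    reliability_threshold: float = 0.6
    max_len: int = 10
    top_k: int = 5
    overgen: int = 20
    max_pops: int = 200_000
    n_background_samples: int = 100_000
    window: int = 5
    n_perm: int = 1000
    significance_cutoff: float = 0.05
    start_gene: str | None = None
    compute_pathway_pvalues: bool = False
    seed: int = 17
    output_dir: str = "trsnet_out"
    _validators: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        checks = {
            "deg_cutoff": 0.0 <= self.deg_cutoff <= 1.0,
            "reliability_threshold": 0.0 <= self.reliability_threshold <= 1.0,
            "max_len": self.max_len >= 1,
            "top_k": self.top_k >= 1,
            "n_background_samples": self.n_background_samples >= 1000,
            "window": self.window >= 1,
            "n_perm": self.n_perm >= 1,
            "significance_cutoff": 0.0 <= self.significance_cutoff <= 1.0,
            "seed": self.seed is not None,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config parameters out of range: {bad}")
        for name in ("expression", "ppi", "starts", "ends"):
            if getattr(self, name) is None:
                raise ValueError(f"config field {name!r} is required")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if not k.startswith("_")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def load_network(cfg: RunConfig) -> nm.OmicsNetwork:
    """Build + annotate + filter the network from the configured files."""
    def edges(path):
        if path is None:
            return None
        if str(path).endswith(".sif"):
            return formats.read_sif(path)
        return formats.read_edge_table(path)

    net = nm.build_network(ppi_edges=edges(cfg.ppi), pd_edges=edges(cfg.pd_edges),
                           kegg_ppi=edges(cfg.kegg_ppi), kegg_pd=edges(cfg.kegg_pd))
    if cfg.localization:
        net = nm.attach_localizations(net, formats.read_localization(cfg.localization))
    net = nm.assign_roles(net, formats.read_roles(cfg.starts),
                          formats.read_roles(cfg.ends))
    net = nm.localization_filter(net)
    net = nm.attach_expression(net, formats.read_expression(cfg.expression),
                               deg_cutoff=cfg.deg_cutoff)
    if cfg.reliability:
        from .reliability import filter_by_reliability
        rel = formats.read_reliability(cfg.reliability)
        net = filter_by_reliability(net, rel, threshold=cfg.reliability_threshold)
    return net


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured discovery run; returns the result bundle."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng_seed.spawn(4)]

    net = _stage("build_network")(load_network)(cfg)
    logger.info("network: %d nodes, %d edges after filtering",
                net.n_nodes, net.n_edges)

    @_stage("backgrounds")
    def backgrounds():
        z_pool = [net.node(n).get("z_score", 0.0) for n in sorted(net.nodes())]
        rel_pool = [d["reliability"] for _, _, _, d in net.edges(kind=nm.PPI)
                    if d.get("reliability") is not None]
        if not rel_pool:
            rel_pool = [1.0] * max(cfg.max_len + 1, 16)  # unit-reliability fallback
        bg_nodes = scoring.build_background(
            z_pool, k_max=cfg.max_len + 1, n_samples=cfg.n_background_samples,
            window=cfg.window, seed=seeds[0], kind="node_z")
        bg_edges = scoring.build_background(
            rel_pool, k_max=cfg.max_len, n_samples=cfg.n_background_samples,
            window=cfg.window, seed=seeds[1], kind="edge_reliability")
        return bg_nodes, bg_edges

    bg_nodes, bg_edges = backgrounds()
    bg_nodes.to_tsv(outdir / "background_nodes.tsv")
    bg_edges.to_tsv(outdir / "background_edges.tsv")

    @_stage("pathway_search")
    def pathways_():
        paths = find_trs_pathways(net, bg_nodes, bg_edges, max_len=cfg.max_len,
                                  top_k=cfg.top_k, overgen=cfg.overgen,
                                  max_pops=cfg.max_pops)
        if cfg.compute_pathway_pvalues:
            paths = [pw.with_pvalue(pathway_pvalue(
                pw, net, bg_nodes, bg_edges, n_perm=cfg.n_perm, seed=seeds[2],
                max_len=cfg.max_len, overgen=cfg.overgen,
                max_pops=cfg.max_pops)) for pw in paths]
        return paths

    pathways = pathways_()
    formats.write_pathways(pathways, outdir / "pathways.tsv")
    logger.info("pathway search: %d pathways", len(pathways))

    result = {"net": net, "bg_nodes": bg_nodes, "bg_edges": bg_edges,
              "pathways": pathways, "network": None}
    if pathways:
        @_stage("network_growth")
        def network_():
            g = grow_trs_network(
                net, pathways, start_gene=cfg.start_gene,
                significance_cutoff=cfg.significance_cutoff)
            z_pool = [net.node(n).get("z_score", 0.0) for n in sorted(net.nodes())]
            k = len(g.nodes)
            if k in bg_nodes:
                bg = bg_nodes
            else:
                bg = scoring.build_background(
                    z_pool, sizes=[k], n_samples=max(cfg.n_background_samples
                                                     // 10, 1000),
                    window=1, seed=seeds[3], kind="node_z")
            return score_trs_network(g, net, bg)

        g = network_()
        result["network"] = g
        with open(outdir / "network_components.tsv", "w") as fh:
            fh.write("seed_gene\tSF\tS\tP_sum\tn_edges\tn_nodes\tp_value\n")
            fh.write(f"{g.seed_gene}\t{g.SF:.6g}\t{g.S:.6g}\t{g.P_sum:.6g}\t"
                     f"{g.n_edges}\t{len(g.nodes)}\tNA\n")
        sub = nm.OmicsNetwork(net.graph.subgraph(g.nodes).copy())
        formats.export_graphml(sub, outdir / "trs_network.graphml")

    manifest = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if not k.startswith("_")},
        "config_digest": cfg.digest(),
        "stage_seeds": seeds,
        "input_digests": {
            name: _file_digest(getattr(cfg, name))
            for name in ("ppi", "pd_edges", "kegg_ppi", "kegg_pd", "localization",
                         "starts", "ends", "expression", "reliability")
            if getattr(cfg, name)
        },
        "network": {"n_nodes": net.n_nodes, "n_edges": net.n_edges},
        "n_pathways": len(pathways),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    result["manifest"] = manifest
    return result
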