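"""Synthetic omics scenarios with planted signaling pathways.

The generator emulates the statistical structure the discovery method
assumes: a degree-heterogeneous PPI background with TF -> target PD edges,
subcellular localization layered along the signal direction, start/end
roles, and an expression experiment in which the members of one or more
planted membrane-to-nucleus chains are transcriptionally shifted while the
background genes are null.  Two planted chains can be joined by a PD
cross-link from the first chain's transcription factor to the second
chain's start protein — the transcription-mediated cross-talk motif the
network growth step is designed to recover.

Per-edge reliabilities are attached directly (planted edges 0.95,
background edges Beta(5, 2)); they are a synthetic stand-in for the output
of the reliability model so that the search modules can be exercised on
their own.  :func:`generate_reliability_data` separately simulates feature/
label pairs from known logistic coefficients for the reliability module's
recovery tests.

Everything is deterministic given the scenario seed, and
:func:`write_scenario` emits exactly the TSV formats the readers consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import network_model as nm
from .network_model import OmicsNetwork

logger = logging.getLogger(__name__)

_COMPARTMENTS = ["extracellular", "plasma_membrane", "cytoplasm", "nucleus", "other"]
_COMPARTMENT_P = [0.08, 0.22, 0.40, 0.22, 0.08]


@dataclass
class PlantedScenario:
    """Study conditions for one synthetic experiment.

    ``planted_paths`` lists (node chain or None, effect size); a None chain
    is auto-allocated as a 5-gene membrane -> cytoplasm -> nucleus chain.
    ``effect`` is the mean shift of the member deviates z ~ Normal(effect, 1);
    background genes are standard normal (so a fraction ``deg_cutoff`` of
    them are spurious DEGs by chance), and ``deg_fraction_null`` optionally
    shifts that many extra background genes.
    """

    n_genes: int = 300
    n_ppi: int = 1500
    n_pd: int = 150
    planted_paths: list = field(default_factory=lambda: [(None, 2.5), (None, 2.5)])
    cross_link: bool = True
    deg_fraction_null: float = 0.0
    n_decoy_starts: int = 4
    n_decoy_ends: int = 4
    chain_length: int = 5
    seed: int = 0


def default_scenario(seed: int = 0, **overrides) -> PlantedScenario:
    return PlantedScenario(seed=seed, **overrides)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _resolve_chains(sc: PlantedScenario, genes: list[str]) -> list[tuple]:
    chains = []
    cursor = 0
    for chain, effect in sc.planted_paths:
        if chain is None:
            chain = tuple(genes[cursor:cursor + sc.chain_length])
            cursor += sc.chain_length
        else:
            chain = tuple(chain)
        if len(chain) < 2 or len(chain) - 1 > 10:
            raise ValueError("planted chains must have 2..11 nodes")
        if effect < 0:
            raise ValueError("effect size must be non-negative")
        chains.append((chain, float(effect)))
    total = sum(len(c) for c, _ in chains)
    if sc.n_genes < total:
        raise ValueError("scenario has fewer genes than planted nodes")
    return chains


def generate_network(sc: PlantedScenario):
    """Build the scenario's omics network and its file-shaped tables.

    Returns ``(net, tables)`` where ``net`` is a fully annotated
    :class:`OmicsNetwork` (localizations, roles, per-PPI reliabilities) and
    ``tables`` maps file stems (ppi, pd, localization, starts, ends,
    reliability) to DataFrames/lists mirroring :func:`write_scenario`.
    """
    rng = np.random.default_rng([sc.seed, 0])
    genes = _gene_names(sc.n_genes)
    chains = _resolve_chains(sc, genes)
    planted_nodes = [g for c, _ in chains for g in c]
    planted_set = set(planted_nodes)

    # localizations: chains layered membrane -> cytoplasm -> nucleus;
    # background genes drawn from a compartment mix, some bi-localized
    locs: dict[str, set] = {}
    for chain, _ in chains:
        locs[chain[0]] = {"plasma_membrane"}
        for g in chain[1:-1]:
            locs[g] = {"cytoplasm"}
        locs[chain[-1]] = {"nucleus"}
    for g in genes:
        if g in locs:
            continue
        primary = rng.choice(len(_COMPARTMENTS), p=_COMPARTMENT_P)
        locs[g] = {_COMPARTMENTS[primary]}
        if rng.random() < 0.15:
            locs[g].add(_COMPARTMENTS[min(primary + 1, 4)])

    # roles: planted termini + random decoys drawn from plausible layers
    starts = [c[0] for c, _ in chains]
    ends = [c[-1] for c, _ in chains]
    membrane = [g for g in genes if g not in planted_set
                and locs[g] & {"extracellular", "plasma_membrane"}]
    nuclear = [g for g in genes if g not in planted_set and "nucleus" in locs[g]]
    if sc.n_decoy_starts:
        starts += list(rng.choice(membrane, size=min(sc.n_decoy_starts,
                                                     len(membrane)), replace=False))
    if sc.n_decoy_ends:
        ends += list(rng.choice(nuclear, size=min(sc.n_decoy_ends,
                                                  len(nuclear)), replace=False))

    # degree-heterogeneous PPI background (configuration-model-like):
    # endpoint propensities follow a Pareto tail to mimic PPI hubs
    weights = rng.pareto(2.0, size=sc.n_genes) + 1.0
    weights /= weights.sum()
    ppi_pairs: set[tuple[str, str]] = set()
    for chain, _ in chains:
        for u, v in zip(chain[:-1], chain[1:]):
            ppi_pairs.add((min(u, v), max(u, v)))
    n_planted_ppi = len(ppi_pairs)
    guard = 0
    while len(ppi_pairs) < n_planted_ppi + sc.n_ppi and guard < 50 * sc.n_ppi:
        u, v = rng.choice(sc.n_genes, size=2, p=weights)
        guard += 1
        if u == v:
            continue
        gu, gv = genes[u], genes[v]
        ppi_pairs.add((min(gu, gv), max(gu, gv)))

    # PD edges: TF pool = planted TFs + random nuclear genes
    tf_pool = ends[:len(chains)] + list(
        rng.choice(nuclear, size=min(10, len(nuclear)), replace=False))
    pd_pairs: set[tuple[str, str]] = set()
    if sc.cross_link and len(chains) >= 2:
        pd_pairs.add((chains[0][0][-1], chains[1][0][0]))
    guard = 0
    while len(pd_pairs) < int(sc.cross_link and len(chains) >= 2) + sc.n_pd \
            and guard < 50 * max(sc.n_pd, 1):
        tf = tf_pool[rng.integers(len(tf_pool))]
        target = genes[rng.choice(sc.n_genes, p=weights)]
        guard += 1
        if tf != target:
            pd_pairs.add((tf, target))

    # reliabilities: planted chain edges near-certain, everything else
    # (including chance background edges among planted genes) Beta(5, 2)
    chain_edges = {(min(u, v), max(u, v)) for chain, _ in chains
                   for u, v in zip(chain[:-1], chain[1:])}
    rel = {}
    for u, v in sorted(ppi_pairs):
        rel[(u, v)] = 0.95 if (u, v) in chain_edges \
            else float(rng.beta(5.0, 2.0))

    ppi_df = pd.DataFrame(sorted(ppi_pairs), columns=["source", "target"])
    ppi_df["kind"] = "PPI"
    ppi_df["provenance"] = "synthetic"
    ppi_df["paper_count"] = rng.poisson(1.5, size=len(ppi_df))
    pd_df = pd.DataFrame(sorted(pd_pairs), columns=["source", "target"])
    pd_df["kind"] = "PD"
    pd_df["provenance"] = "synthetic"
    pd_df["paper_count"] = 0
    pd_df["pd_sign"] = "unknown"
    loc_df = pd.DataFrame(
        [(g, l) for g in genes for l in sorted(locs[g])],
        columns=["gene_id", "localization"])
    rel_df = pd.DataFrame(
        [(u, v, r) for (u, v), r in sorted(rel.items())],
        columns=["source", "target", "mean_reliability"])

    net = nm.build_network(ppi_edges=ppi_df, pd_edges=pd_df)
    for g in genes:
        net.add_gene(g)
    net = nm.attach_localizations(net, loc_df)
    if starts and ends:
        net = nm.assign_roles(net, starts, ends)
    else:
        logger.info("scenario has no start/end roles (null expression study)")
    for u, v, kind, data in net.edges(kind=nm.PPI):
        data["reliability"] = rel[(min(u, v), max(u, v))]

    tables = {"ppi": ppi_df, "pd": pd_df, "localization": loc_df,
              "starts": sorted(set(starts)), "ends": sorted(set(ends)),
              "reliability": rel_df, "chains": chains}
    return net, tables


def generate_expression(sc: PlantedScenario, net: OmicsNetwork) -> pd.DataFrame:
    """Expression table (gene_id, p_value, log_fold_change) for the scenario.

    Background genes: z ~ N(0, 1), so p = 1 - Phi(z) is uniform.  Planted
    members: z ~ N(effect, 1).  A ``deg_fraction_null`` fraction of extra
    background genes receives the largest planted effect (spurious DEGs).
    Log fold change shares the sign of z.
    """
    rng = np.random.default_rng([sc.seed, 1])
    genes = sorted(net.nodes())
    chains = _resolve_chains(sc, _gene_names(sc.n_genes))
    effect = {g: eff for chain, eff in chains for g in chain}
    z = rng.standard_normal(len(genes))
    max_eff = max((eff for _, eff in chains), default=0.0)
    for i, g in enumerate(genes):
        if g in effect:
            z[i] += effect[g]
        elif sc.deg_fraction_null > 0 and rng.random() < sc.deg_fraction_null:
            z[i] += max_eff
    p = stats.norm.sf(z).clip(1e-16, 1 - 1e-16)
    lfc = z * rng.uniform(0.3, 0.7, size=len(genes))
    return pd.DataFrame({"gene_id": genes, "p_value": p,
                         "log_fold_change": lfc})


def generate_reliability_data(sc: PlantedScenario, true_betas,
                              n_pairs: int = 5000):
    """Simulated (features, labels) from known logistic coefficients.

    Features mimic the observed ranges: paper counts ~ Poisson(2),
    expression correlation ~ Uniform(-1, 1), clustering ~ Uniform(0, 1),
    co-localization ~ Bernoulli(0.5).  Labels are Bernoulli of the logistic
    mean, enabling coefficient-recovery tests.
    """
    true_betas = np.asarray(true_betas, dtype=float)
    if true_betas.shape != (5,):
        raise ValueError("true_betas must have five entries (beta_0..beta_4)")
    rng = np.random.default_rng([sc.seed, 2])
    X = np.column_stack([
        rng.poisson(2.0, n_pairs).astype(float),
        rng.uniform(-1.0, 1.0, n_pairs),
        rng.uniform(0.0, 1.0, n_pairs),
        rng.integers(0, 2, n_pairs).astype(float),
    ])
    eta = true_betas[0] + X @ true_betas[1:]
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n_pairs) < prob).astype(int)
    features = pd.DataFrame(X, columns=["paper_count", "expr_corr",
                                        "clustering", "coloc"])
    return features, y


def realize_scenario(sc: PlantedScenario, deg_cutoff: float = 0.05,
                     reliability_threshold: float = 0.6):
    """Generate and fully prepare a scenario for the search modules.

    Runs the standard preparation chain — localization filter, reliability
    filter at the given floor, expression attachment — and returns
    ``(net, tables, expr_table)``.
    """
    from .reliability import filter_by_reliability

    net, tables = generate_network(sc)
    expr = generate_expression(sc, net)
    net = nm.localization_filter(net)
    rel = {(min(u, v), max(u, v)): d["reliability"]
           for u, v, _, d in net.edges(kind=nm.PPI)}
    net = filter_by_reliability(net, rel, threshold=reliability_threshold)
    net = nm.attach_expression(net, expr, deg_cutoff=deg_cutoff)
    return net, tables, expr


def write_scenario(sc: PlantedScenario, outdir) -> dict:
    """Write every scenario file (TSV / id lists / manifest); returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, tables = generate_network(sc)
    expr = generate_expression(sc, net)
    paths = {}
    for stem in ("ppi", "pd", "localization", "reliability"):
        paths[stem] = outdir / f"{stem}.tsv"
        tables[stem].to_csv(paths[stem], sep="\t", index=False)
    for stem in ("starts", "ends"):
        paths[stem] = outdir / f"{stem}.txt"
        paths[stem].write_text("".join(f"{g}\n" for g in tables[stem]))
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)
    manifest = {
        "n_genes": sc.n_genes, "n_ppi": sc.n_ppi, "n_pd": sc.n_pd,
        "planted_chains": [list(c) for c, _ in tables["chains"]],
        "effect_sizes": [e for _, e in tables["chains"]],
        "cross_link": sc.cross_link, "seed": sc.seed,
    }
    paths["manifest"] = outdir / "scenario.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
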