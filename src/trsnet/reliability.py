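"""Logistic-regression reliability of protein-protein interactions.

Reported PPIs are noisy, so each undirected pair is scored with the
probability of being a true interaction under a logistic model on four
observed features: the number of papers reporting the interaction, the
Pearson correlation of the two genes' expression profiles, the pair's
small-world clustering statistic on the undirected PPI graph, and a binary
co-localization flag.  The model is refit on many resampled trainings drawn
from positive (e.g. co-immunoprecipitation-supported) and negative
(non-interacting) pair pools, and the mean predicted probability over
repeats is the edge's reliability.  Edges below a reliability floor
(default 0.6) are removed before path search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import statsmodels.api as sm

from .network_model import OmicsNetwork, PPI

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeFeatures:
    """Feature vector of one undirected PPI pair."""

    paper_count: int
    expr_corr: float
    clustering: float
    coloc: int

    def as_array(self) -> np.ndarray:
        return np.array([self.paper_count, self.expr_corr, self.clustering,
                         self.coloc], dtype=float)


@dataclass
class ReliabilityModel:
    """Mean logistic coefficients and per-edge mean reliabilities."""

    betas: np.ndarray                    # mean (beta_0..beta_4) over repeats
    n_repeats: int
    mean_reliability: dict               # sorted (u, v) pair -> mean prob
    sd_reliability: dict                 # sorted (u, v) pair -> SD over repeats


def _pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def compute_edge_features(net: OmicsNetwork, expr_matrix=None,
                          lit_counts=None) -> dict:
    """One :class:`EdgeFeatures` per undirected PPI pair of the network.

    ``expr_matrix`` is a genes x samples DataFrame (missing profiles give
    correlation 0); ``lit_counts`` maps a pair to its paper count and falls
    back to the edge's own ``paper_count`` attribute, then 0.  The
    clustering statistic of a pair is the mean of the two endpoints' local
    clustering coefficients on the undirected PPI graph; co-localization is
    1 iff the nodes share at least one annotated compartment.
    """
    pairs: dict[tuple[str, str], int] = {}
    for u, v, _, data in net.edges(kind=PPI):
        key = _pair(u, v)
        pairs[key] = max(pairs.get(key, 0), int(data.get("paper_count", 0)))

    undirected = nx.Graph()
    undirected.add_nodes_from(net.nodes())
    undirected.add_edges_from(pairs)
    clustering = nx.clustering(undirected)

    profiles = None
    if expr_matrix is not None:
        profiles = {str(g): np.asarray(row, dtype=float)
                    for g, row in zip(expr_matrix.index, expr_matrix.values)}

    features = {}
    for (u, v), attr_count in sorted(pairs.items()):
        if lit_counts is not None and _pair(u, v) in lit_counts:
            count = int(lit_counts[_pair(u, v)])
        else:
            count = attr_count
        corr = 0.0
        if profiles is not None and u in profiles and v in profiles:
            a, b = profiles[u], profiles[v]
            if a.std() > 0 and b.std() > 0:
                corr = float(np.corrcoef(a, b)[0, 1])
        locs_u = net.node(u).get("localizations", frozenset())
        locs_v = net.node(v).get("localizations", frozenset())
        coloc = 1 if locs_u & locs_v else 0
        features[(u, v)] = EdgeFeatures(
            paper_count=count,
            expr_corr=corr,
            clustering=(clustering[u] + clustering[v]) / 2.0,
            coloc=coloc,
        )
    return features


def _ridge_logistic_irls(exog: np.ndarray, y: np.ndarray, alpha: float = 1e-8,
                         max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """IRLS logistic fit with a tiny L2 penalty; separation-proof fallback."""
    beta = np.zeros(exog.shape[1])
    pen = alpha * np.eye(exog.shape[1])
    for _ in range(max_iter):
        eta = np.clip(exog @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = exog.T @ (y - mu) - alpha * beta
        hess = (exog * w[:, None]).T @ exog + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_reliability_model(features, labels, return_se: bool = False):
    """Maximum-likelihood logistic coefficients (beta_0..beta_4).

    ``features`` is an (n, 4) array or a list of :class:`EdgeFeatures`;
    ``labels`` are binary.  The problem is convex, so the fit is
    deterministic given the data.  Perfect separation triggers a logged
    fallback to a tiny-ridge (1e-8) IRLS fit.
    """
    if isinstance(features, (list, tuple)) and features \
            and isinstance(features[0], EdgeFeatures):
        X = np.vstack([f.as_array() for f in features])
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("fit_reliability_model: both classes must be present")
    exog = np.column_stack([np.ones(len(y)), X])

    betas = bse = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged") and np.all(np.isfinite(res.params)) \
                and np.all(np.isfinite(res.bse)):
            betas, bse = np.asarray(res.params), np.asarray(res.bse)
    except Exception:  # separation, singular Hessian, ...
        pass
    if betas is None:
        logger.warning("logistic fit did not converge (separation?); "
                       "using ridge-IRLS fallback with alpha=1e-8")
        betas = _ridge_logistic_irls(exog, y)
        eta = np.clip(exog @ betas, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        cov = np.linalg.pinv((exog * w[:, None]).T @ exog)
        bse = np.sqrt(np.diag(cov))
    return (betas, bse) if return_se else betas


def _predict(betas: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(betas[0] + X @ betas[1:], -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def estimate_mean_reliability(net: OmicsNetwork, features: dict, positives,
                              negatives, n_repeats: int = 1000,
                              n_train: int = 5000,
                              seed: int | None = None) -> ReliabilityModel:
    """Mean per-PPI reliability over resampled logistic trainings.

    Each repeat draws ``n_train`` positive and ``n_train`` negative pairs
    (with replacement when a pool is smaller than ``n_train``, logged), fits
    the logistic model, and scores every PPI pair of the network; the mean
    and SD over repeats are stored.  Deterministic given ``seed``.
    """
    pos = sorted(_pair(*p) for p in positives)
    neg = sorted(_pair(*p) for p in negatives)
    if not pos or not neg:
        raise ValueError("positive and negative pools must be non-empty")

    def fmat(keys):
        return np.vstack([features[k].as_array() for k in keys])

    all_pairs = sorted(features)
    X_all = fmat(all_pairs)
    X_pos, X_neg = fmat(pos), fmat(neg)

    rng = np.random.default_rng(seed)
    acc = np.zeros(len(all_pairs))
    acc2 = np.zeros(len(all_pairs))
    beta_sum = np.zeros(5)
    for pool, name in ((pos, "positive"), (neg, "negative")):
        if len(pool) < n_train:
            logger.info("%s pool (%d) smaller than n_train=%d; sampling with "
                        "replacement", name, len(pool), n_train)
    for _ in range(n_repeats):
        i_pos = rng.choice(len(pos), size=n_train, replace=len(pos) < n_train)
        i_neg = rng.choice(len(neg), size=n_train, replace=len(neg) < n_train)
        X = np.vstack([X_pos[i_pos], X_neg[i_neg]])
        y = np.concatenate([np.ones(n_train), np.zeros(n_train)])
        betas = fit_reliability_model(X, y)
        beta_sum += betas
        probs = _predict(betas, X_all)
        acc += probs
        acc2 += probs ** 2
    mean = acc / n_repeats
    var = np.clip(acc2 / n_repeats - mean ** 2, 0.0, None)
    return ReliabilityModel(
        betas=beta_sum / n_repeats,
        n_repeats=n_repeats,
        mean_reliability=dict(zip(all_pairs, mean.tolist())),
        sd_reliability=dict(zip(all_pairs, np.sqrt(var).tolist())),
    )


def filter_by_reliability(net: OmicsNetwork, model, threshold: float = 0.6,
                          exempt_provenance=None) -> OmicsNetwork:
    """Remove PPI edges whose mean reliability is below ``threshold``.

    ``model`` is a :class:`ReliabilityModel` or a plain pair -> reliability
    mapping.  Retained PPI edges gain a ``reliability`` attribute; edges not
    covered by the model are removed (logged).  PD edges are untouched.
    Edges whose provenance intersects ``exempt_provenance`` (e.g. curated
    pathway databases) bypass the cut.
    """
    rel = model.mean_reliability if isinstance(model, ReliabilityModel) else dict(model)
    rel = {_pair(*k): v for k, v in rel.items()}
    exempt = set(exempt_provenance or ())
    out = net.copy()
    dropped = uncovered = 0
    for u, v, kind, data in list(out.edges(kind=PPI)):
        r = rel.get(_pair(u, v))
        if r is None:
            out.graph.remove_edge(u, v, key=kind)
            uncovered += 1
            continue
        data["reliability"] = float(r)
        if r < threshold and not (exempt & data.get("provenance", set())):
            out.graph.remove_edge(u, v, key=kind)
            dropped += 1
    logger.info("filter_by_reliability: dropped %d PPI edges below %.2f "
                "(%d uncovered)", dropped, threshold, uncovered)
    return out
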