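"""Expression and reliability scoring with Monte-Carlo background correction.

The per-gene statistic is the normal deviate ``Z_i = Phi^{-1}(1 - p_i)`` of a
differential-expression p-value.  A candidate pathway with node set ``N``
aggregates these into

    Z_N = sum_i Z_i / sqrt(|N|)

and the aggregate is standardised against a Monte-Carlo background: for each
set size ``k`` the mean ``mu_k`` and standard deviation ``sigma_k`` of the
aggregate over random size-``k`` gene sets are estimated (100,000 samples by
default), de-noised with a centred sliding-window average across sizes, and
the corrected score is

    S(N) = (Z_N - mu_k) / sigma_k,     k = |N|.

By construction a random gene set has corrected score mean 0 and SD 1.  The
same machinery corrects the aggregate of per-edge PPI reliabilities, giving
the pathway reliability score R(E).  The pathway score adds the raw start
and end deviates so that paths whose termini are themselves induced rank
higher:

    T(N) = S(N) + Z_start + Z_end,     P(N, E) = T(N) + R(E).

A grown network with expression score S, member pathway scores ``P_i`` and
``|E|`` edges is summarised by the composite

    SF = (S + sum_i P_i) / |E|,

which rewards transcriptional perturbation and significant pathway content
while penalising sheer size; the functional form is isolated here so it can
be swapped without touching the search code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_EPS = 1e-16


def z_from_p(p: float) -> float:
    """Normal deviate of a p-value: ``Phi^{-1}(1 - p)``.

    p = 0.5 maps to 0; smaller p to larger z.  Values at or beyond the open
    interval (0, 1) are clamped to [1e-16, 1 - 1e-16] and logged, so z stays
    finite.
    """
    p = float(p)
    if p <= 0.0 or p >= 1.0:
        logger.debug("z_from_p: clamping boundary p=%g", p)
        p = min(max(p, _EPS), 1.0 - _EPS)
    return float(stats.norm.isf(p))


def aggregate_z(z_values: Sequence[float]) -> float:
    """Size-normalised aggregate ``sum(z) / sqrt(k)`` over a gene set."""
    arr = np.asarray(z_values, dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_z: empty value list")
    return float(arr.sum() / math.sqrt(arr.size))


# ---------------------------------------------------------------------------
# Monte-Carlo background tables


@dataclass
class BackgroundTable:
    """Per-size Monte-Carlo mean/SD of the aggregate score over random sets.

    ``mu``/``sigma`` are the raw estimates, ``mu_s``/``sigma_s`` the
    sliding-window smoothed ones actually used for correction.  Smoothing is
    meaningful when ``sizes`` are contiguous; arbitrary size lists are
    smoothed across adjacent entries of the list.
    """

    kind: str
    sizes: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    mu_s: np.ndarray
    sigma_s: np.ndarray
    n_samples: int
    window: int
    seed: int | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {int(k): i for i, k in enumerate(self.sizes)}

    @property
    def k_max(self) -> int:
        return int(self.sizes.max())

    def __contains__(self, k: int) -> bool:
        return int(k) in self._index

    def params(self, k: int) -> tuple[float, float]:
        try:
            i = self._index[int(k)]
        except KeyError:
            raise KeyError(
                f"background table ({self.kind}) has no entry for set size {k}; "
                f"available sizes {sorted(self._index)}") from None
        return float(self.mu_s[i]), float(self.sigma_s[i])

    # -- serialization (TSV with '#'-prefixed metadata header) -------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n# n_samples={self.n_samples}\n")
            fh.write(f"# window={self.window}\n# seed={self.seed}\n")
            fh.write("k\tmu\tsigma\tmu_smoothed\tsigma_smoothed\n")
            for i, k in enumerate(self.sizes):
                fh.write(f"{int(k)}\t{self.mu[i]:.10g}\t{self.sigma[i]:.10g}\t"
                         f"{self.mu_s[i]:.10g}\t{self.sigma_s[i]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "BackgroundTable":
        meta, rows = {}, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                elif line and not line.startswith("k\t"):
                    rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        seed = meta.get("seed")
        return cls(
            kind=meta.get("kind", "node_z"),
            sizes=arr[:, 0].astype(int),
            mu=arr[:, 1], sigma=arr[:, 2], mu_s=arr[:, 3], sigma_s=arr[:, 4],
            n_samples=int(meta.get("n_samples", 0)),
            window=int(meta.get("window", 1)),
            seed=None if seed in (None, "None") else int(seed),
        )


def _sample_index_matrix(rng: np.random.Generator, pool_size: int, k: int,
                         n_samples: int) -> np.ndarray:
    """(n_samples, k) index matrix of without-replacement draws.

    Rejection resampling of duplicate rows is cheap while k << pool_size;
    for dense draws a random-key argsort is used instead.
    """
    if k == 1:
        return rng.integers(0, pool_size, size=(n_samples, 1))
    if k * 8 >= pool_size:
        keys = rng.random((n_samples, pool_size))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx = rng.integers(0, pool_size, size=(n_samples, k))
    while True:
        sorted_idx = np.sort(idx, axis=1)
        bad = (np.diff(sorted_idx, axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, pool_size, size=(int(bad.sum()), k))


def _sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average of width ``window``, truncated at the ends."""
    if window <= 1:
        return x.copy()
    h = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        out[i] = x[max(0, i - h):i + h + 1].mean()
    return out


def build_background(
    pool: Sequence[float],
    k_max: int | None = None,
    n_samples: int = 100_000,
    window: int = 5,
    seed: int | None = None,
    kind: str = "node_z",
    sizes: Iterable[int] | None = None,
) -> BackgroundTable:
    """Estimate ``mu_k``/``sigma_k`` of the aggregate score by Monte Carlo.

    For each set size (``1..k_max`` by default, or an explicit ``sizes``
    list) draws ``n_samples`` random subsets of the value pool without
    replacement, aggregates each with :func:`aggregate_z`, and records mean
    and SD; both sequences are then smoothed across adjacent sizes with a
    centred window.  A degenerate pool (zero SD after smoothing) is an
    error.  Reproducible given ``seed``.
    """
    pool = np.asarray(pool, dtype=float)
    size_list = sorted(int(k) for k in sizes) if sizes is not None else list(
        range(1, int(k_max) + 1))
    if not size_list:
        raise ValueError("no set sizes requested")
    if pool.size < max(size_list):
        raise ValueError(
            f"pool of {pool.size} values cannot supply sets of size {max(size_list)}")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for stable estimates")

    rng = np.random.default_rng(seed)
    mu = np.empty(len(size_list))
    sigma = np.empty(len(size_list))
    for i, k in enumerate(size_list):
        idx = _sample_index_matrix(rng, pool.size, k, n_samples)
        agg = pool[idx].sum(axis=1) / math.sqrt(k)
        mu[i] = agg.mean()
        sigma[i] = agg.std(ddof=0)

    mu_s = _sliding_mean(mu, window)
    sigma_s = _sliding_mean(sigma, window)
    if np.any(sigma_s <= 1e-9 * np.maximum(1.0, np.abs(mu_s))):
        raise ValueError("degenerate value pool: zero background SD after smoothing")
    return BackgroundTable(kind=kind, sizes=np.asarray(size_list), mu=mu,
                           sigma=sigma, mu_s=mu_s, sigma_s=sigma_s,
                           n_samples=n_samples, window=window, seed=seed)


def corrected_score(raw: float, k: int, bg: BackgroundTable) -> float:
    """Standardise an aggregate against its size-k background: (raw-mu)/sigma."""
    mu, sigma = bg.params(k)
    return (float(raw) - mu) / sigma


# ---------------------------------------------------------------------------
# pathway and network scores


@dataclass(frozen=True)
class PathScore:
    """T/R decomposition of a pathway score; P is exactly their sum."""

    T: float
    R: float

    @property
    def P(self) -> float:
        return self.T + self.R


def path_expression_score(z_values: Sequence[float], bg_nodes: BackgroundTable) -> float:
    """Expression component ``T = S(N) + Z_start + Z_end`` of a path.

    ``z_values`` are the member deviates in path order (at least two nodes).
    Adding the raw terminal deviates favours paths whose initiating ligand /
    receptor and terminal transcription factor are themselves induced.
    """
    if len(z_values) < 2:
        raise ValueError("a path needs at least two nodes")
    s = corrected_score(aggregate_z(z_values), len(z_values), bg_nodes)
    return s + float(z_values[0]) + float(z_values[-1])


def path_reliability_score(reliabilities: Sequence[float],
                           bg_edges: BackgroundTable) -> float:
    """Reliability component R(E) over a path's PPI edges.

    Protein-DNA edges carry no reliability and are excluded by the caller; a
    path with no PPI edges scores R = 0.
    """
    if len(reliabilities) == 0:
        return 0.0
    return corrected_score(aggregate_z(reliabilities), len(reliabilities), bg_edges)


def path_score(T: float, R: float) -> PathScore:
    return PathScore(T=float(T), R=float(R))


def network_score(S: float, pathway_scores: Sequence[float], n_edges: int) -> float:
    """Composite network score ``SF = (S + sum of pathway scores) / n_edges``."""
    if n_edges < 1:
        raise ValueError("network_score needs at least one edge")
    return (float(S) + float(np.sum(pathway_scores))) / float(n_edges)


def format_pvalue(p: float, n_perm: int) -> str:
    """Table-style rendering of a permutation p-value.

    A score exceeding every permutation is reported as a bound, e.g.
    ``"<1.0e-03"`` at 1,000 permutations.
    """
    if p * (n_perm + 1) <= 1.0 + 1e-9:
        return f"<{1.0 / n_perm:.1e}"
    return f"{p:.3g}"
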