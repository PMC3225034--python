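"""Edge features, logistic fitting, resampled reliability, and the 0.6 floor."""

import math

import numpy as np
import pandas as pd
import pytest

from trsnet import (build_network, attach_localizations, compute_edge_features,
                    estimate_mean_reliability, filter_by_reliability,
                    fit_reliability_model)
from trsnet.network_model import PD, PPI

from conftest import make_net


def irls_logistic_oracle(X, y, iters=60):
    """Plain Newton/IRLS logistic fit used as the independent oracle."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(iters):
        mu = 1.0 / (1.0 + np.exp(-np.clip(Z @ beta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        beta = beta + np.linalg.solve((Z * w[:, None]).T @ Z, Z.T @ (y - mu))
    cov = np.linalg.inv((Z * w[:, None]).T @ Z)
    return beta, np.sqrt(np.diag(cov))


class TestEdgeFeatures:
    def test_shared_compartment_gives_coloc_one(self):
        net = build_network(ppi_edges=[("A", "B"), ("C", "D")])
        net = attach_localizations(net, {"A": {"cytoplasm"},
                                         "B": {"cytoplasm", "nucleus"},
                                         "C": {"nucleus"},
                                         "D": {"cytoplasm"}})
        feats = compute_edge_features(net)
        assert feats[("A", "B")].coloc == 1
        assert feats[("C", "D")].coloc == 0

    def test_identical_profiles_give_correlation_one(self):
        net = build_network(ppi_edges=[("A", "B")])
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]],
                           index=["A", "B"])
        feats = compute_edge_features(net, expr_matrix=mat)
        assert feats[("A", "B")].expr_corr == pytest.approx(1.0)

    def test_missing_profile_defaults_to_zero(self):
        net = build_network(ppi_edges=[("A", "B")])
        mat = pd.DataFrame([[1.0, 2.0]], index=["A"])
        assert compute_edge_features(net, expr_matrix=mat)[("A", "B")].expr_corr == 0.0

    def test_triangle_pair_has_clustering_one(self):
        # both endpoints' neighborhoods are cliques in a closed triangle
        net = build_network(ppi_edges=[("A", "B"), ("B", "C"), ("A", "C")])
        feats = compute_edge_features(net)
        assert feats[("A", "B")].clustering == pytest.approx(1.0)

    def test_paper_count_falls_back_to_edge_attribute(self):
        net = build_network(ppi_edges=[("A", "B", "x", 7)])
        assert compute_edge_features(net)[("A", "B")].paper_count == 7
        forced = compute_edge_features(net, lit_counts={("A", "B"): 2})
        assert forced[("A", "B")].paper_count == 2


class TestFitReliabilityModel:
    def test_balanced_intercept_only_fit_is_zero(self):
        X = np.zeros((100, 4))
        y = np.array([1, 0] * 50)
        betas = fit_reliability_model(X, y)
        assert np.allclose(betas, 0.0, atol=1e-6)

    def test_unbalanced_intercept_is_log_odds(self):
        X = np.zeros((100, 4))
        y = np.array([1] * 75 + [0] * 25)
        betas = fit_reliability_model(X, y)
        assert betas[0] == pytest.approx(math.log(3.0), abs=1e-6)

    def test_recovers_known_betas_within_three_se(self):
        rng = np.random.default_rng(42)
        true = np.array([-0.5, 0.8, -1.2, 2.0, 0.6])
        X = np.column_stack([rng.poisson(2.0, 5000), rng.uniform(-1, 1, 5000),
                             rng.uniform(0, 1, 5000), rng.integers(0, 2, 5000)])
        eta = true[0] + X @ true[1:]
        y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(float)
        betas, se = fit_reliability_model(X, y, return_se=True)
        assert np.all(np.abs(betas - true) <= 3 * se)
        # and the implementation agrees with an independent IRLS oracle
        oracle, _ = irls_logistic_oracle(X, y)
        assert np.allclose(betas, oracle, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_reliability_model(np.zeros((10, 4)), np.ones(10))

    def test_perfect_separation_falls_back_to_ridge(self):
        X = np.zeros((40, 4))
        X[:20, 0] = 1.0
        y = np.array([1.0] * 20 + [0.0] * 20)
        betas = fit_reliability_model(X, y)
        assert np.all(np.isfinite(betas)) and betas[1] > 5.0


class TestEstimateMeanReliability:
    def setup_net(self):
        # 21 genes -> 20 pairs, so the positive and negative pools have
        # equal size and one full-pool repeat reproduces a single fit
        ppi = []
        genes = [f"g{i}" for i in range(21)]
        for i in range(20):
            ppi.append((genes[i], genes[i + 1], 0.8))
        net = make_net(ppi=ppi)
        feats = compute_edge_features(net)
        pairs = sorted(feats)
        # plant separation: positives get coloc-like high features
        from trsnet.reliability import EdgeFeatures
        for i, p in enumerate(pairs):
            if i % 2 == 0:
                feats[p] = EdgeFeatures(paper_count=5, expr_corr=0.9,
                                        clustering=0.8, coloc=1)
        pos = [p for i, p in enumerate(pairs) if i % 2 == 0]
        neg = [p for i, p in enumerate(pairs) if i % 2 == 1]
        return net, feats, pos, neg

    def test_single_repeat_equals_single_fit(self):
        net, feats, pos, neg = self.setup_net()
        model = estimate_mean_reliability(net, feats, pos, neg, n_repeats=1,
                                          n_train=len(pos), seed=1)
        X = np.vstack([feats[p].as_array() for p in sorted(feats)])
        betas = fit_reliability_model(
            np.vstack([feats[p].as_array() for p in pos]
                      + [feats[p].as_array() for p in neg]),
            np.array([1.0] * len(pos) + [0.0] * len(neg)))
        expected = 1 / (1 + np.exp(-(betas[0] + X @ betas[1:])))
        got = np.array([model.mean_reliability[p] for p in sorted(feats)])
        assert np.allclose(got, expected, atol=1e-9)

    def test_reliabilities_bounded_and_separated(self):
        net, feats, pos, neg = self.setup_net()
        model = estimate_mean_reliability(net, feats, pos, neg, n_repeats=20,
                                          n_train=8, seed=2)
        vals = np.array(list(model.mean_reliability.values()))
        assert np.all((vals >= 0) & (vals <= 1))
        # an edge sharing the strongly positive feature profile scores > 0.5
        assert model.mean_reliability[pos[0]] > 0.5

    def test_deterministic_given_seed(self):
        net, feats, pos, neg = self.setup_net()
        a = estimate_mean_reliability(net, feats, pos, neg, n_repeats=5,
                                      n_train=8, seed=3)
        b = estimate_mean_reliability(net, feats, pos, neg, n_repeats=5,
                                      n_train=8, seed=3)
        assert a.mean_reliability == b.mean_reliability

    def test_empty_pool_is_an_error(self):
        net, feats, pos, neg = self.setup_net()
        with pytest.raises(ValueError):
            estimate_mean_reliability(net, feats, [], neg)


class TestFilterByReliability:
    def test_strict_threshold_semantics(self):
        net = make_net(ppi=[("A", "B"), ("C", "D")], pd=[("E", "F")])
        rel = {("A", "B"): 0.59, ("C", "D"): 0.60}
        out = filter_by_reliability(net, rel, threshold=0.6)
        assert not out.has_edge("A", "B", PPI)
        assert out.has_edge("C", "D", PPI)
        assert out.has_edge("E", "F", PD)

    def test_uncovered_ppi_edges_removed(self):
        net = make_net(ppi=[("A", "B")])
        out = filter_by_reliability(net, {}, threshold=0.6)
        assert out.n_edges == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(9)
        ppi = [(f"a{i}", f"b{i}") for i in range(30)]
        net = make_net(ppi=ppi)
        rel = {tuple(sorted(p)): rng.uniform(0, 1) for p in ppi}
        kept = None
        for thr in (0.2, 0.5, 0.8):
            out = filter_by_reliability(net, rel, threshold=thr)
            edges = {(u, v) for u, v, _, _ in out.edges(kind=PPI)}
            if kept is not None:
                assert edges <= kept
            kept = edges

    def test_provenance_exemption(self):
        net = build_network(kegg_ppi=[("A", "B")])
        out = filter_by_reliability(net, {("A", "B"): 0.1}, threshold=0.6,
                                    exempt_provenance={"kegg"})
        assert out.has_edge("A", "B", PPI)
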