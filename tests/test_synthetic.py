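"""Planted-scenario generator: determinism, structure, and calibration."""

import filecmp

import numpy as np
import pytest
from scipy.stats import norm

from trsnet import build_network, fit_reliability_model
from trsnet.network_model import PD, PPI
from trsnet.synthetic import (PlantedScenario, default_scenario,
                              generate_expression, generate_network,
                              generate_reliability_data, realize_scenario,
                              write_scenario)


class TestGenerateNetwork:
    def test_planted_chains_exist_as_directed_paths(self):
        net, tables = generate_network(default_scenario(seed=5))
        for chain, _ in tables["chains"]:
            for u, v in zip(chain[:-1], chain[1:]):
                assert net.has_edge(u, v, PPI)

    def test_zero_background_scenario_has_only_planted_edges(self):
        sc = PlantedScenario(n_genes=10, n_ppi=0, n_pd=0, cross_link=False,
                             n_decoy_starts=0, n_decoy_ends=0, seed=1)
        net, tables = generate_network(sc)
        ppi = {(u, v) for u, v, k, _ in net.edges(kind=PPI)}
        expected = set()
        for chain, _ in tables["chains"]:
            for u, v in zip(chain[:-1], chain[1:]):
                expected |= {(u, v), (v, u)}
        assert ppi == expected

    def test_cross_link_pd_edge_present(self):
        net, tables = generate_network(default_scenario(seed=2))
        (c1, _), (c2, _) = tables["chains"]
        assert net.has_edge(c1[-1], c2[0], PD)

    def test_chain_layering_respects_signal_direction(self):
        net, tables = generate_network(default_scenario(seed=3))
        for chain, _ in tables["chains"]:
            assert net.node(chain[0])["localizations"] == {"plasma_membrane"}
            assert net.node(chain[-1])["localizations"] == {"nucleus"}
            assert "start" in net.roles_of(chain[0])
            assert "end" in net.roles_of(chain[-1])

    def test_infeasible_scenario_rejected(self):
        with pytest.raises(ValueError):
            generate_network(PlantedScenario(n_genes=4, seed=1))

    def test_planted_chain_edges_survive_standard_filters(self):
        net, tables, _ = realize_scenario(default_scenario(seed=4))
        for chain, _ in tables["chains"]:
            for u, v in zip(chain[:-1], chain[1:]):
                assert net.has_edge(u, v, PPI)
                assert net.edge(u, v, PPI)["reliability"] >= 0.6


class TestGenerateExpression:
    def test_effect_three_deg_rate_matches_normal_tail(self):
        # P(z > 1.645 | z ~ N(3, 1)) = Phi(3 - 1.645) ~ 0.912
        hits = total = 0
        for seed in range(3):
            sc = PlantedScenario(
                n_genes=400, n_ppi=0, n_pd=0, cross_link=False,
                planted_paths=[(None, 3.0)] * 30, n_decoy_starts=0,
                n_decoy_ends=0, seed=seed)
            net, tables = generate_network(sc)
            expr = generate_expression(sc, net).set_index("gene_id")
            members = [g for chain, _ in tables["chains"] for g in chain]
            hits += int((expr.loc[members, "p_value"] < 0.05).sum())
            total += len(members)
        assert hits / total == pytest.approx(norm.cdf(3.0 - norm.isf(0.05)),
                                             abs=0.05)

    def test_null_background_deg_fraction_matches_cutoff(self):
        sc = PlantedScenario(n_genes=2000, n_ppi=0, n_pd=0, planted_paths=[],
                             cross_link=False, n_decoy_starts=0,
                             n_decoy_ends=0, seed=8)
        net, _ = generate_network(sc)
        expr = generate_expression(sc, net)
        assert (expr["p_value"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_logfc_sign_matches_z_sign(self):
        sc = default_scenario(seed=9)
        net, _ = generate_network(sc)
        expr = generate_expression(sc, net)
        z = norm.isf(expr["p_value"])
        assert np.all(np.sign(expr["log_fold_change"]) == np.sign(z))

    def test_spurious_deg_fraction_raises_rate(self):
        base = PlantedScenario(n_genes=2000, n_ppi=0, n_pd=0, planted_paths=[],
                               cross_link=False, n_decoy_starts=0,
                               n_decoy_ends=0, seed=10)
        spiked = PlantedScenario(**{**base.__dict__, "deg_fraction_null": 0.2,
                                    "planted_paths": [(None, 3.0)]})
        net, _ = generate_network(base)
        rate0 = (generate_expression(base, net)["p_value"] < 0.05).mean()
        net2, _ = generate_network(spiked)
        rate1 = (generate_expression(spiked, net2)["p_value"] < 0.05).mean()
        assert rate1 > rate0 + 0.1


class TestReliabilityData:
    def test_zero_betas_give_half_label_rate(self):
        _, y = generate_reliability_data(default_scenario(seed=1),
                                         np.zeros(5), n_pairs=5000)
        assert y.mean() == pytest.approx(0.5, abs=0.03)

    def test_coloc_coefficient_drives_coloc_labels(self):
        X, y = generate_reliability_data(default_scenario(seed=2),
                                         [0, 0, 0, 0, 3.0], n_pairs=4000)
        coloc = X["coloc"].to_numpy() == 1
        assert y[coloc].mean() > y[~coloc].mean() + 0.3

    def test_mle_recovers_generating_betas(self):
        true = np.array([-0.3, 0.5, -1.0, 1.5, 0.8])
        X, y = generate_reliability_data(default_scenario(seed=3), true,
                                         n_pairs=5000)
        betas, se = fit_reliability_model(X.to_numpy(), y, return_se=True)
        assert np.all(np.abs(betas - true) <= 3 * se)


class TestRoundTrip:
    def test_written_files_are_byte_identical_across_runs(self, tmp_path):
        sc = PlantedScenario(n_genes=60, n_ppi=120, n_pd=15, seed=6)
        p1 = write_scenario(sc, tmp_path / "a")
        p2 = write_scenario(sc, tmp_path / "b")
        for stem in p1:
            assert filecmp.cmp(p1[stem], p2[stem], shallow=False), stem

    def test_files_round_trip_through_the_readers(self, tmp_path):
        from trsnet import formats
        from trsnet import network_model as nm

        sc = PlantedScenario(n_genes=60, n_ppi=120, n_pd=15, seed=7)
        paths = write_scenario(sc, tmp_path / "s")
        net_mem, tables = generate_network(sc)

        ppi = formats.read_edge_table(paths["ppi"])
        pd_edges = formats.read_edge_table(paths["pd"])
        net = build_network(ppi_edges=ppi, pd_edges=pd_edges)
        net = nm.attach_localizations(
            net, formats.read_localization(paths["localization"]))
        net = nm.assign_roles(net, formats.read_roles(paths["starts"]),
                              formats.read_roles(paths["ends"]))
        assert {(u, v, k) for u, v, k, _ in net.edges()} == \
            {(u, v, k) for u, v, k, _ in net_mem.edges()}
        for g in net.nodes():
            assert net.node(g)["localizations"] == \
                net_mem.node(g)["localizations"]
            assert net.roles_of(g) == net_mem.roles_of(g)
        rel = formats.read_reliability(paths["reliability"])
        for u, v, _, d in net_mem.edges(kind=PPI):
            assert rel[(min(u, v), max(u, v))] == pytest.approx(
                d["reliability"], abs=5e-7)
        expr = formats.read_expression(paths["expression"])
        assert set(expr["gene_id"]) == set(net_mem.nodes())
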