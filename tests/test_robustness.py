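import itertools

import numpy as np
import pandas as pd
import pytest

import coralnet as cn
from coralnet.robustness import RemovalModel, removal_order, removal_trajectory, r50

from conftest import make_records, set_tolerances, star_network
from test_bleaching import random_toy_network


def matching_network(toy_env, n_pairs=6):
    rows = [(f"Coral sp{i:02d}", "North Reef", f"S{i:02d}") for i in range(n_pairs)]
    return cn.build_network(make_records(rows), toy_env)


class TestRemovalModel:
    def test_mode_only_for_susceptible_links(self):
        with pytest.raises(ValueError):
            RemovalModel("random_links", mode="host")
        with pytest.raises(ValueError):
            RemovalModel("susceptible_links")  # mode required
        with pytest.raises(ValueError):
            RemovalModel("frobnicate")

    def test_parse_cli_labels(self):
        m = RemovalModel.parse("susceptible-links:host")
        assert m.kind == "susceptible_links" and m.mode == "host"
        assert RemovalModel.parse("random-nodes").kind == "random_nodes"


class TestRemovalOrder:
    def test_random_links_is_a_permutation(self, toy_net):
        net = set_tolerances(toy_net.copy())
        order = removal_order(net, RemovalModel("random_links"),
                              np.random.default_rng(0))
        canon = lambda edges: sorted(tuple(sorted(e)) for e in edges)
        assert canon(order) == canon(net.edges())

    def test_host_mode_groups_links_by_host(self, toy_env):
        rng = np.random.default_rng(1)
        net = random_toy_network(rng, toy_env)
        # make host tolerances distinct so grouping is forced
        hosts = [n for n, d in net.nodes(data=True) if d["kind"] == "host"]
        for i, h in enumerate(sorted(hosts)):
            net.nodes[h]["tolerance"] = (i + 1) / (len(hosts) + 1)
        order = removal_order(net, RemovalModel("susceptible_links", mode="host"), rng)
        owners = [u if net.nodes[u]["kind"] == "host" else v for u, v in order]
        seen, last = set(), None
        for h in owners:
            if h != last:
                assert h not in seen  # once a host's block ends it never reopens
                seen.add(h)
            last = h

    def test_bleaching_equals_averaged_susceptibility_with_one_t_mmm(self, toy_env):
        rng = np.random.default_rng(2)
        net = cn.build_network(
            make_records([(f"Coral sp{i}", "North Reef", f"S{j}")
                          for i in range(4) for j in range(3)]),
            toy_env,
        )
        tol_rng = np.random.default_rng(42)  # distinct values, tie-free sums
        for n in sorted(net.nodes):
            net.nodes[n]["tolerance"] = float(tol_rng.random())
        order_b = removal_order(net, RemovalModel("bleaching"), rng)
        order_s = removal_order(net, RemovalModel("susceptible_links", mode="averaged"), rng)
        assert order_b == order_s  # W is a monotone transform of the average

    def test_susceptible_nodes_pools_both_classes_ascending(self, toy_net):
        net = set_tolerances(toy_net.copy())
        for i, n in enumerate(sorted(net.nodes)):
            net.nodes[n]["tolerance"] = (i + 1) / 10
        order = removal_order(net, RemovalModel("susceptible_nodes"),
                              np.random.default_rng(0))
        tols = [net.nodes[n]["tolerance"] for n in order]
        assert tols == sorted(tols)
        kinds = {net.nodes[n]["kind"] for n in order}
        assert kinds == {"host", "symbiont"}

    def test_bleaching_without_tolerances_is_an_error(self, toy_net):
        with pytest.raises(ValueError, match="tolerance"):
            removal_order(toy_net.copy(), RemovalModel("bleaching"),
                          np.random.default_rng(0))


class TestTrajectoryAndR50:
    def test_star_link_removal_enumeration(self, toy_env):
        net = star_network(toy_env, 10)
        order = removal_order(set_tolerances(net), RemovalModel("random_links"),
                              np.random.default_rng(3))
        traj = removal_trajectory(net, order)
        # after k<10 removals, 11-k nodes remain; at k=10 the hub isolates too
        expected = [11 - k for k in range(10)] + [0]
        assert traj.remaining_counts.tolist() == expected
        assert r50(traj) == pytest.approx(0.6)

    def test_star_hub_node_removal_cascades(self, toy_env):
        net = star_network(toy_env, 10)
        traj = removal_trajectory(net, ["HUB"], entity="nodes")
        assert traj.remaining_counts.tolist() == [11, 0]

    def test_empty_order_is_flat(self, toy_net):
        traj = removal_trajectory(toy_net, [], entity="links")
        assert traj.remaining_counts.tolist() == [toy_net.number_of_nodes()]
        assert traj.fractions_remaining[0] == 1.0

    def test_unknown_entity_rejected(self, toy_net):
        with pytest.raises(KeyError):
            removal_trajectory(toy_net, ["NOT A NODE"], entity="nodes")

    def test_matching_r50_is_half(self, toy_env):
        net = matching_network(toy_env, 6)
        order = removal_order(set_tolerances(net), RemovalModel("random_links"),
                              np.random.default_rng(0))
        assert r50(removal_trajectory(net, order)) == pytest.approx(0.5)

    def test_trajectories_monotone_and_complete(self, toy_env):
        rng = np.random.default_rng(11)
        for kind in ("random_links", "random_nodes"):
            net = random_toy_network(rng, toy_env)
            order = removal_order(net, RemovalModel(kind), rng)
            traj = removal_trajectory(net, order)
            assert np.all(np.diff(traj.remaining_counts) <= 0)
            assert traj.remaining_counts[-1] == 0
            assert 0 < r50(traj) <= 1

    def test_random_link_r50_matches_exhaustive_permutation_oracle(self, toy_env):
        net = cn.build_network(
            make_records(
                [("Coral a", "North Reef", "S1"), ("Coral a", "North Reef", "S2"),
                 ("Coral b", "North Reef", "S1"), ("Coral b", "North Reef", "S3"),
                 ("Coral c", "North Reef", "S2"), ("Coral d", "North Reef", "S2"),
                 ("Coral d", "North Reef", "S3")]
            ),
            toy_env,
        )
        edges = list(net.edges())
        exact = np.mean(
            [r50(removal_trajectory(net, list(p), entity="links"))
             for p in itertools.permutations(edges)]
        )
        rng = np.random.default_rng(21)
        sample = [
            r50(removal_trajectory(
                net, removal_order(set_tolerances(net.copy()),
                                   RemovalModel("random_links"), rng)))
            for _ in range(2000)
        ]
        se = np.std(sample, ddof=1) / np.sqrt(len(sample))
        assert np.mean(sample) == pytest.approx(exact, abs=4 * se + 1e-9)


class TestRobustnessEnsemble:
    def test_deterministic_model_has_zero_spread(self, toy_env):
        net = matching_network(toy_env, 5)
        tables = cn.ToleranceTables(
            host=pd.DataFrame({"species": [f"Coral sp{i:02d}" for i in range(5)],
                               "bri_mean": np.linspace(10, 90, 5),
                               "bri_sd": 0.0}),
            symbiont=pd.DataFrame({"its2_type": [f"S{i:02d}" for i in range(5)],
                                   "genus": ["Cladocopium"] * 5,
                                   "rank_score": np.linspace(5, 95, 5)}),
        )
        res = cn.robustness_ensemble(
            net, RemovalModel("susceptible_links", mode="host"), tables,
            cn.BleachingConfig(replicates=10), seed=0,
        )
        assert res.sd == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_results(self, small_bundle):
        net = small_bundle.network()
        cfg = cn.BleachingConfig(replicates=10)
        runs = [
            cn.robustness_ensemble(net, RemovalModel("bleaching"),
                                   small_bundle.tables, cfg, seed=5,
                                   taxonomy=small_bundle.taxonomy)
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].values, runs[1].values)


class TestFamilySusceptibility:
    def _tables(self, species, bri, symbionts):
        return cn.ToleranceTables(
            host=pd.DataFrame({"species": species, "bri_mean": bri, "bri_sd": 0.0}),
            symbiont=pd.DataFrame({"its2_type": symbionts,
                                   "genus": ["Cladocopium"] * len(symbionts),
                                   "rank_score": 50.0}),
        )

    def _two_family_net(self, toy_env):
        records = []
        for i in range(4):
            records.append(cn.AssociationRecord(
                f"Fragilis sp{i}", "North Reef", "Toy Ocean", "S1",
                host_family="EarlyFam"))
        for i in range(4):
            records.append(cn.AssociationRecord(
                f"Robustus sp{i}", "North Reef", "Toy Ocean", "S2",
                host_family="LateFam"))
        return cn.build_network(records, toy_env)

    def test_fragile_family_always_first_and_tough_family_never(self, toy_env):
        net = self._two_family_net(toy_env)
        species = [f"Fragilis sp{i}" for i in range(4)] + [f"Robustus sp{i}" for i in range(4)]
        tables = self._tables(species, [95.0] * 4 + [5.0] * 4, ["S1", "S2"])
        out = cn.family_susceptibility(net, tables,
                                       cn.BleachingConfig(replicates=5),
                                       seed=3, n_first=4)
        assert out.by_family == {"EarlyFam": 4}
        assert "LateFam" not in out.by_family
        assert out.by_subregion == {"North Reef": 4}

    def test_single_replicate_is_that_replicates_first_set(self, small_bundle):
        net = small_bundle.network()
        cfg = cn.BleachingConfig(replicates=1)
        with pytest.warns(UserWarning):
            out = cn.family_susceptibility(net, small_bundle.tables, cfg, seed=9,
                                           taxonomy=small_bundle.taxonomy, n_first=50)
        assert len(out.hosts) == min(50, 40)
        assert sum(out.by_family.values()) == len(out.hosts)
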