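"""Bipartite network construction, modularity, annealing and the null model."""

import numpy as np
import pytest

import dactynet as dn
from dactynet.data_model import DataValidationError
from dactynet.network import (
    BipartiteNetwork,
    SASchedule,
    build_network,
    detect_modules,
    modularity,
    randomize,
    significance,
)
from oracle_utils import exhaustive_best_partition, random_pruned_incidence


def star_pair():
    """Two disconnected stars: A–{1,2}, B–{3,4}."""
    inc = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
    return BipartiteNetwork(["A", "B"], ["f1", "f2", "f3", "f4"], inc)


class TestBuildNetwork:
    def test_identity_incidence(self):
        net = build_network({"A": {"f1"}, "B": {"f2"}})
        assert net.L == 2
        assert np.array_equal(net.incidence, np.eye(2, dtype=np.int8))

    def test_shared_everything(self):
        net = build_network({"A": {"f1", "f2"}, "B": {"f1", "f2"}})
        assert net.L == 4
        assert net.incidence.all()

    def test_link_count_matches_counting_oracle(self, filtered_paperlike):
        filtered, meta, _, _ = filtered_paperlike
        prev = dn.prevalence_by_group(filtered, meta, "species")
        net = build_network(prev)
        assert net.L == sum(len(v) for v in prev.values())
        degs = net.degrees
        for sp, otus in prev.items():
            assert degs[sp] == len(otus)

    def test_empty_prevalence_and_pruning(self):
        with pytest.raises(DataValidationError):
            build_network({})
        with pytest.warns(UserWarning):
            net = build_network({"A": {"f1"}, "B": set()})
        assert net.species_ids == ["A"]


class TestModularityFormula:
    def test_single_module_is_zero(self):
        net = star_pair()
        assign = {u: 0 for u in net.node_ids}
        assert modularity(net, assign) == pytest.approx(0.0, abs=1e-15)

    def test_two_by_two_matching_partitions(self):
        net = build_network({"A": {"f1"}, "B": {"f2"}})
        good = {"A": 0, "f1": 0, "B": 1, "f2": 1}
        bad = {"A": 0, "f2": 0, "B": 1, "f1": 1}
        assert modularity(net, good) == pytest.approx(0.5, abs=1e-12)
        assert modularity(net, bad) == pytest.approx(-0.5, abs=1e-12)

    def test_disconnected_stars_component_partition(self):
        net = star_pair()
        assign = {"A": 0, "f1": 0, "f2": 0, "B": 1, "f3": 1, "f4": 1}
        assert modularity(net, assign) == pytest.approx(0.5, abs=1e-12)

    def test_missing_node_rejected(self):
        net = star_pair()
        with pytest.raises(DataValidationError):
            modularity(net, {"A": 0})

    def test_upper_bound_and_degree_sum_invariant(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            inc = random_pruned_incidence(rng)
            net = BipartiteNetwork(
                [f"s{i}" for i in range(inc.shape[0])],
                [f"o{j}" for j in range(inc.shape[1])],
                inc,
            )
            part = detect_modules(net, seed=trial)
            assert part.M <= 1 - 1 / part.n_modules + 1e-12
            assert sum(part.d_s) == 2 * net.L
            assert sum(part.l_s) <= net.L


class TestDetectModules:
    def test_recovers_disconnected_stars(self):
        part = detect_modules(star_pair(), seed=1)
        assert part.n_modules == 2
        assert part.M == pytest.approx(0.5, abs=1e-12)
        assert part.assignment["A"] == part.assignment["f1"] == part.assignment["f2"]

    @pytest.mark.parametrize("size", [2, 3])
    def test_complete_bipartite_single_module(self, size):
        inc = np.ones((size, size), dtype=np.int8)
        net = BipartiteNetwork(
            [f"s{i}" for i in range(size)], [f"o{j}" for j in range(size)], inc
        )
        best, _ = exhaustive_best_partition(inc)
        part = detect_modules(net, seed=3)
        assert part.M == pytest.approx(best, abs=1e-12)
        # the optimum of a complete bipartite graph is M = 0, attained by the
        # single-module partition (among other tied partitions, e.g. perfect
        # matchings, which score 0 as well)
        assert part.M == pytest.approx(0.0, abs=1e-12)
        assert modularity(net, {u: 0 for u in net.node_ids}) == pytest.approx(
            part.M, abs=1e-12
        )

    def test_returned_M_consistent_with_formula(self):
        rng = np.random.default_rng(5)
        inc = random_pruned_incidence(rng)
        net = BipartiteNetwork(
            [f"s{i}" for i in range(inc.shape[0])],
            [f"o{j}" for j in range(inc.shape[1])],
            inc,
        )
        part = detect_modules(net, seed=11)
        assert modularity(net, part.assignment) == pytest.approx(part.M, abs=1e-12)

    def test_deterministic_given_seed_and_canonical_labels(self):
        net = star_pair()
        a = detect_modules(net, seed=42)
        b = detect_modules(net, seed=42)
        assert a.assignment == b.assignment and a.M == b.M
        # canonical labels: module indices 0..K-1, size-descending
        sizes = [len(m) for m in a.module_members()]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_schedule_rejected(self):
        with pytest.raises(ValueError):
            SASchedule(cooling=1.5)


class TestRandomize:
    def test_unique_swap_two_by_two(self):
        inc = np.array([[1, 0], [0, 1]], dtype=np.int8)
        net = BipartiteNetwork(["A", "B"], ["f1", "f2"], inc)
        seen = set()
        for s in range(20):
            r = randomize(net, n_swaps=50, seed=s)
            seen.add(tuple(r.incidence.flatten()))
            assert np.array_equal(r.incidence.sum(1), [1, 1])
            assert np.array_equal(r.incidence.sum(0), [1, 1])
        assert seen == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_all_ones_has_no_checkerboard(self):
        inc = np.ones((3, 3), dtype=np.int8)
        net = BipartiteNetwork(["A", "B", "C"], ["f1", "f2", "f3"], inc)
        with pytest.warns(UserWarning):
            r = randomize(net, seed=0)
        assert np.array_equal(r.incidence, inc)

    def test_margins_preserved_on_every_draw(self, filtered_paperlike):
        filtered, meta, _, _ = filtered_paperlike
        net = build_network(dn.prevalence_by_group(filtered, meta, "species"))
        rs, cs = net.incidence.sum(1), net.incidence.sum(0)
        for s in range(20):
            r = randomize(net, seed=s)
            assert np.array_equal(r.incidence.sum(1), rs)
            assert np.array_equal(r.incidence.sum(0), cs)


class TestSignificance:
    def test_planted_blocks_reach_p_floor(self):
        cfg = dn.SimConfig(
            populations_per_species=(3,) * 10 + (2,) * 4,
            p_between=0.0,
            generalist_fraction=0.0,
            rare_otu_rate=0.0,
            seed=3,
        )
        table, meta, tax, truth = dn.simulate(cfg)
        net = build_network(truth.planted_prevalence)
        sig = significance(net, n_null=19, seed=5)
        assert sig.p_value == pytest.approx(1 / 20)
        assert sig.M_obs > sig.null_mean

    def test_p_value_definition_and_recomputable_moments(self):
        net = star_pair()
        sig = significance(net, n_null=19, seed=1)
        arr = np.array(sig.null_Ms)
        assert sig.null_mean == pytest.approx(arr.mean())
        assert sig.null_sd == pytest.approx(arr.std(ddof=1))
        expect_p = (1 + (arr >= sig.M_obs - 1e-12).sum()) / 20
        assert sig.p_value == pytest.approx(expect_p)
        with pytest.raises(ValueError):
            significance(net, n_null=0, seed=1)
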