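"""IndVal components, best habitat combinations and permutation inference."""

from itertools import permutations

import numpy as np
import pytest

import dactynet as dn
from dactynet.indicators import (
    best_combination,
    indicator_test,
    indval_components,
)
from oracle_utils import all_unions, brute_force_indval


def table_of(counts, n_otus=None):
    counts = np.asarray(counts)
    return dn.OtuTable(
        [f"s{i}" for i in range(counts.shape[0])],
        [f"o{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestComponents:
    def test_perfect_indicator(self):
        t = table_of([[5], [5], [0], [0]])
        g = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        A, B = indval_components(t, g, {"A"})["o0"]
        assert A == pytest.approx(1.0) and B == pytest.approx(1.0)

    def test_ubiquitous_equal_over_two_groups(self):
        t = table_of([[4], [4], [4], [4]])
        g = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        A, B = indval_components(t, g, {"A"})["o0"]
        assert A == pytest.approx(0.5) and B == pytest.approx(1.0)
        (res,) = best_combination(t, g, max_order=1)
        assert res.ind_val == pytest.approx(np.sqrt(0.5))

    def test_absent_from_target_gives_zero(self):
        t = table_of([[0], [0], [3], [3]])
        g = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        A, B = indval_components(t, g, {"A"})["o0"]
        assert B == 0.0 and np.sqrt(max(A, 0) * B) == 0.0

    def test_absent_everywhere_is_not_applicable(self):
        t = table_of([[0, 1], [0, 2], [0, 1], [0, 3]])
        g = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        A, _ = indval_components(t, g, {"A"})["o0"]
        assert np.isnan(A)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(3, size=(12, 7))
        counts[0] += 1  # no empty site
        t = table_of(counts)
        labels = [["A", "B", "C"][i % 3] for i in range(12)]
        g = {f"s{i}": labels[i] for i in range(12)}
        for target in ({"A"}, {"B", "C"}):
            mine = indval_components(t, g, target, relative_abundance=False)
            ref = brute_force_indval(counts.astype(float), labels, target)
            for j in range(7):
                A, B = mine[f"o{j}"]
                assert A == pytest.approx(ref[j][0], abs=1e-12)
                assert B == pytest.approx(ref[j][1], abs=1e-12)

    def test_scale_invariance_of_indval(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2, size=(9, 4)) + 1
        t = table_of(counts)
        g = {f"s{i}": ["A", "B", "C"][i % 3] for i in range(9)}
        base = best_combination(t, g, relative_abundance=False)
        scaled = table_of(counts * np.array([1, 7, 3, 11]))
        res = best_combination(scaled, g, relative_abundance=False)
        for r0, r1 in zip(base, res):
            assert r1.ind_val == pytest.approx(r0.ind_val, abs=1e-12)
            assert r1.best_group == r0.best_group


class TestBestCombination:
    def test_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2, size=(16, 6))
        counts[:, 0] += 1
        t = table_of(counts)
        habs = ["A", "B", "C", "D"]
        g = {f"s{i}": habs[i % 4] for i in range(16)}
        results = best_combination(t, g, relative_abundance=False)
        for r in results:
            if not r.applicable:
                continue
            vals = {}
            for union in all_unions(habs, 3):
                comp = indval_components(t, g, union, relative_abundance=False)
                A, B = comp[r.otu_id]
                if not np.isnan(A):
                    vals[union] = np.sqrt(A * B)
            best_val = max(vals.values())
            assert r.ind_val == pytest.approx(best_val, abs=1e-12)
            ties = [u for u, v in vals.items() if v >= best_val - 1e-12]
            expect = min(ties, key=lambda u: (len(u), tuple(sorted(u))))
            assert r.best_group == expect

    def test_confined_otu_selects_its_union(self):
        # present evenly in wetland+mediterranean sites only
        counts = np.array([[3], [3], [3], [3], [0], [0]])
        t = table_of(counts)
        g = {
            "s0": "wetland",
            "s1": "wetland",
            "s2": "mediterranean",
            "s3": "mediterranean",
            "s4": "coastal",
            "s5": "coastal",
        }
        (r,) = best_combination(t, g)
        assert r.best_group == frozenset({"wetland", "mediterranean"})
        assert r.ind_val == pytest.approx(1.0)

    def test_single_habitat_otu_selects_singleton(self):
        counts = np.array([[2], [4], [0], [0], [0], [0]])
        t = table_of(counts)
        g = {f"s{i}": ["A", "A", "B", "B", "C", "C"][i] for i in range(6)}
        (r,) = best_combination(t, g)
        assert r.best_group == frozenset({"A"})

    def test_ind_val_squared_equals_A_times_B(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(2, size=(10, 5)) + (rng.random((10, 5)) < 0.3)
        counts[:, 0] += 1
        t = table_of(counts.astype(int))
        g = {f"s{i}": ["A", "B"][i % 2] for i in range(10)}
        for r in best_combination(t, g):
            if r.applicable:
                assert r.ind_val**2 == pytest.approx(r.A * r.B, abs=1e-12)


class TestPermutationInference:
    def test_matches_exhaustive_relabeling_on_six_sites(self):
        counts = np.array([[9], [7], [8], [1], [0], [0]])
        t = table_of(counts)
        labels = ["A", "A", "A", "B", "B", "B"]
        g = {f"s{i}": labels[i] for i in range(6)}
        obs = best_combination(t, g, max_order=1)[0].ind_val

        def stat(perm_labels):
            gp = {f"s{i}": perm_labels[i] for i in range(6)}
            return best_combination(t, gp, max_order=1)[0].ind_val

        vals = [stat(p) for p in permutations(labels)]
        p_exact = np.mean([v >= obs - 1e-12 for v in vals])
        res = indicator_test(t, g, n_perm=4999, seed=0, max_order=1)
        assert res[0].p_value == pytest.approx(p_exact, abs=0.02)

    def test_planted_indicators_significant(self, filtered_paperlike):
        filtered, meta, truth, _ = filtered_paperlike
        sites = dn.aggregate_by_group(
            filtered, meta, attr="population_id", mode="summed_counts"
        )
        groups = {m.population_id: m.habitat.value for m in meta}
        res = indicator_test(sites, groups, n_perm=199, seed=4)
        sig = {r.otu_id for r in res if r.p_value is not None and r.p_value <= 0.05}
        planted = set(truth.planted_indicators)
        assert planted <= sig
        by_id = {r.otu_id: r for r in res}
        for o in planted:
            assert "peat_bog" in by_id[o].best_group

    def test_invalid_n_perm(self, small_table):
        g = {s: "A" if i < 2 else "B" for i, s in enumerate(small_table.sample_ids)}
        with pytest.raises(ValueError):
            indicator_test(small_table, g, n_perm=0)
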