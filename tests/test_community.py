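"""Dissimilarity, NMDS and PERMANOVA behaviour."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

import dactynet as dn
from dactynet.community import aggregate_by_species, dissimilarity, nmds, permanova
from dactynet.data_model import DataValidationError, DistanceMatrix


def meta_row(s, sp, pop="p1", hab="wetland", plo="2x"):
    return dn.SampleMetadata(s, sp, pop, hab, plo, "XX")


class TestAggregation:
    def test_presence_and_sum_modes(self):
        t = dn.OtuTable(["s1", "s2"], ["a", "b"], np.array([[1, 0], [0, 4]]))
        meta = [meta_row("s1", "sp1"), meta_row("s2", "sp1")]
        pres = aggregate_by_species(t, meta, mode="presence")
        assert np.array_equal(pres.counts, [[1, 1]])
        summed = aggregate_by_species(t, meta, mode="summed_counts")
        assert np.array_equal(summed.counts, [[1, 4]])

    def test_sum_matches_group_sum_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(2, size=(12, 8))
        t = dn.OtuTable([f"s{i}" for i in range(12)], [f"o{j}" for j in range(8)], counts)
        meta = [meta_row(f"s{i}", f"sp{i % 4}") for i in range(12)]
        agg = aggregate_by_species(t, meta, mode="summed_counts")
        for g, sp in enumerate(agg.sample_ids):
            members = [i for i in range(12) if f"sp{i % 4}" == sp]
            assert np.array_equal(agg.counts[g], counts[members].sum(axis=0))


class TestDissimilarity:
    def test_identical_and_disjoint_rows(self):
        t = dn.OtuTable(["a", "b", "c"], ["o1", "o2"], np.array([[2, 1], [2, 1], [0, 5]]))
        bc = dissimilarity(t, "bray_curtis")
        assert bc.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        t2 = dn.OtuTable(["a", "b"], ["o1", "o2"], np.array([[3, 0], [0, 7]]))
        for metric in ("bray_curtis", "jaccard"):
            assert dissimilarity(t2, metric).values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_value(self):
        # x=(1,2,0), y=(0,2,4): 1 - 2*2/(3+6) = 5/9
        t = dn.OtuTable(["x", "y"], ["o1", "o2", "o3"], np.array([[1, 2, 0], [0, 2, 4]]))
        d = dissimilarity(t, "bray_curtis")
        assert d.values[0, 1] == pytest.approx(1 - 4 / 9, abs=1e-12)

    def test_bounds_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.5, size=(10, 12)) + np.eye(10, 12, dtype=int)
        t = dn.OtuTable([f"s{i}" for i in range(10)], [f"o{j}" for j in range(12)], counts)
        for metric in ("bray_curtis", "jaccard"):
            d = dissimilarity(t, metric).values
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
            assert np.allclose(d, d.T)
        pres = (counts > 0).astype(int)
        dj = dissimilarity(t, "jaccard").values
        for i in range(10):
            for j in range(10):
                if np.array_equal(pres[i], pres[j]):
                    assert dj[i, j] == pytest.approx(0.0, abs=1e-12)
                else:
                    assert dj[i, j] > 0

    def test_all_zero_row_rejected(self):
        t = dn.OtuTable(["a", "b"], ["o1"], np.array([[0], [3]]))
        with pytest.raises(DataValidationError, match="a"):
            dissimilarity(t, "jaccard")


class TestNmds:
    def test_exactly_embeddable_configurations(self):
        eq = DistanceMatrix(list("abc"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        r = nmds(eq, k=2, n_restarts=5, seed=1)
        assert r.stress == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(r.coordinates.mean(axis=0), 0.0, atol=1e-9)
        two = DistanceMatrix(list("ab"), np.array([[0, 2], [2, 0]], float))
        assert nmds(two, k=1, n_restarts=3, seed=1).stress == pytest.approx(0.0, abs=1e-9)

    def test_k_too_large_rejected(self):
        d = DistanceMatrix(list("abc"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        with pytest.raises(ValueError):
            nmds(d, k=3)

    def test_more_restarts_never_worse_and_near_reference(self):
        rng = np.random.default_rng(3)
        x = rng.random((8, 3))
        d = DistanceMatrix([f"s{i}" for i in range(8)], squareform(pdist(x)))
        few = nmds(d, k=2, n_restarts=20, seed=9).stress
        many = nmds(d, k=2, n_restarts=200, seed=9).stress
        assert many <= few + 1e-12  # restart seeds nest
        assert few - many < 1e-4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.random((7, 2))
        d = DistanceMatrix([f"s{i}" for i in range(7)], squareform(pdist(x)))
        a = nmds(d, k=2, n_restarts=10, seed=5)
        b = nmds(d, k=2, n_restarts=10, seed=5)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates, b.coordinates)


class TestPermanova:
    def test_univariate_two_groups_closed_form(self):
        # {0,1} vs {10,11}: classical one-way ANOVA F = 200
        x = np.array([0.0, 1.0, 10.0, 11.0])
        ids = list("abcd")
        d = DistanceMatrix(ids, squareform(pdist(x[:, None])))
        res = permanova(d, dict(zip(ids, ["g1", "g1", "g2", "g2"])), 99, seed=0)
        assert res.pseudo_F == pytest.approx(200.0, abs=1e-10)
        assert res.df_between == 1 and res.df_within == 2

    def test_equals_anova_f_on_random_univariate_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 15))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=n)
            labels = rng.integers(0, k, size=n)
            while len(set(labels)) < k or np.bincount(labels, minlength=k).min() < 2:
                labels = rng.integers(0, k, size=n)
            ids = [f"s{i}" for i in range(n)]
            d = DistanceMatrix(ids, squareform(pdist(x[:, None])))
            res = permanova(d, {i: str(g) for i, g in zip(ids, labels)}, 9, seed=1)
            F = f_oneway(*[x[labels == g] for g in range(k)]).statistic
            assert res.pseudo_F == pytest.approx(F, abs=1e-10)

    def test_invariant_to_relabeling_and_row_order(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(9, 4))
        ids = [f"s{i}" for i in range(9)]
        d = DistanceMatrix(ids, squareform(pdist(x)))
        groups = {i: ("u" if int(i[1:]) % 2 else "v") for i in ids}
        base = permanova(d, groups, 99, seed=3).pseudo_F
        renamed = permanova(d, {i: g.upper() for i, g in groups.items()}, 99, seed=3)
        assert renamed.pseudo_F == pytest.approx(base, abs=1e-12)
        perm = rng.permutation(9)
        d2 = DistanceMatrix([ids[i] for i in perm], d.values[np.ix_(perm, perm)])
        assert permanova(d2, groups, 99, seed=3).pseudo_F == pytest.approx(base, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        d = DistanceMatrix(list("abcd"), squareform([1.0, 1, 1, 1, 1, 1]))
        with pytest.raises(DataValidationError):
            permanova(d, {i: "same" for i in "abcd"}, 99)
        zero_within = DistanceMatrix(
            list("abcd"), squareform([0.0, 1, 1, 1, 1, 0.0])
        )
        with pytest.raises(DataValidationError):
            permanova(zero_within, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, 99)

    def test_p_value_floor_and_range(self):
        x = np.array([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
        ids = [f"s{i}" for i in range(6)]
        d = DistanceMatrix(ids, squareform(pdist(x[:, None])))
        groups = dict(zip(ids, ["a", "a", "b", "b", "c", "c"]))
        res = permanova(d, groups, n_permutations=999, seed=2)
        assert 1 / 1000 <= res.p_value <= 1

    def test_agrees_with_skbio_reference(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 5))
        ids = [f"s{i}" for i in range(10)]
        vals = squareform(pdist(x))
        groups = ["a"] * 5 + ["b"] * 5
        mine = permanova(dn.DistanceMatrix(ids, vals), dict(zip(ids, groups)), 99, seed=1)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(vals, ids), grouping=groups, permutations=99
        )
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)
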