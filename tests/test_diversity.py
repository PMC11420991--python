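import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from myconet.diversity import (
    DistanceMatrix,
    ace,
    alpha_diversity,
    bray_curtis,
    dominant_phyla,
    euclidean_distance,
    hellinger,
    mantel,
    nmds,
    rarefy,
    shannon,
)
from myconet.io import CountTable, TaxonomyTable


class TestRarefy:
    def test_all_depths_equal_minimum(self):
        t = CountTable(
            ["a", "b", "c"],
            ["o1", "o2"],
            np.array([[60, 40], [30, 20], [50, 30]]),
        )
        out = rarefy(t, seed=0)
        assert (out.depths() == 50).all()

    def test_never_increases_counts(self):
        rng = np.random.default_rng(5)
        t = CountTable(
            ["a", "b"], [f"o{i}" for i in range(20)],
            rng.integers(0, 50, size=(2, 20)),
        )
        out = rarefy(t, seed=1)
        assert (out.counts <= t.counts).all()

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        t = CountTable(
            ["a", "b"], [f"o{i}" for i in range(10)],
            rng.integers(1, 30, size=(2, 10)),
        )
        assert rarefy(t, seed=9) == rarefy(t, seed=9)

    def test_single_sample_unchanged(self):
        t = CountTable(["a"], ["o1", "o2"], np.array([[3, 7]]))
        assert rarefy(t, seed=0) == t

    def test_zero_depth_sample_rejected(self):
        t = CountTable(["a", "b"], ["o1"], np.array([[5], [0]]))
        with pytest.raises(ValueError, match="zero depth"):
            rarefy(t)


class TestShannon:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((1, 1, 1, 1), np.log(4)),
            ((7, 0, 0), 0.0),
            ((1, 1, 2), 1.0397207708399179),  # -sum p ln p evaluated directly
        ],
    )
    def test_known_values(self, row, expected):
        assert shannon(np.array(row)) == pytest.approx(expected, abs=1e-12)

    def test_base_conversion(self):
        assert shannon(np.array([1, 1]), base=2) == pytest.approx(1.0)

    def test_uniform_is_maximal(self):
        rng = np.random.default_rng(0)
        s = 12
        uniform = shannon(np.full(s, 5))
        for _ in range(20):
            row = rng.integers(1, 100, s)
            assert shannon(row) <= uniform + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon(np.zeros(3))


class TestAce:
    def test_no_rare_species_equals_richness(self):
        assert ace(np.array([11, 20, 300])) == 3.0

    def test_all_singletons_degenerate(self):
        with pytest.raises(ValueError, match="Chao1"):
            ace(np.array([1, 1, 1, 1, 1]))

    def test_matches_independent_formula_coding(self):
        # brute-force transcription of the Chao & Lee estimator
        def ace_oracle(row, cutoff=10):
            row = row[row > 0]
            rare = row[row <= cutoff]
            s_abund = (row > cutoff).sum()
            s_rare = len(rare)
            n_rare = rare.sum()
            f1 = (rare == 1).sum()
            c = 1 - f1 / n_rare
            top = sum(i * (i - 1) * (rare == i).sum() for i in range(1, cutoff + 1))
            g2 = max(s_rare / c * top / (n_rare * (n_rare - 1)) - 1, 0.0)
            return s_abund + s_rare / c + f1 / c * g2

        rows = [
            np.array([1, 1, 2, 3, 5, 8, 13, 21, 40]),
            np.array([1, 2, 2, 4, 9, 10, 11, 50]),
            np.array([3, 3, 3, 12, 80]),
        ]
        for row in rows:
            assert ace(row) == pytest.approx(ace_oracle(row), rel=1e-12)

    def test_matches_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        row = np.array([1, 1, 2, 3, 5, 8, 13, 21, 40, 60])
        assert ace(row) == pytest.approx(float(skbio_alpha.ace(row)), rel=1e-9)

    def test_ace_at_least_observed(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            row = rng.integers(0, 30, size=25)
            if row.sum() == 0:
                continue
            try:
                est = ace(row)
            except ValueError:
                continue
            assert est >= (row > 0).sum() - 1e-9


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = CountTable(["a", "b"], ["o1", "o2"], np.array([[3, 4], [3, 4]]))
        assert bray_curtis(t).d[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        t = CountTable(["a", "b"], ["o1", "o2"], np.array([[5, 0], [0, 9]]))
        assert bray_curtis(t).d[0, 1] == pytest.approx(1.0)

    def test_hand_computed_third(self):
        t = CountTable(["a", "b"], ["o1", "o2"], np.array([[2, 2], [2, 0]]))
        assert bray_curtis(t).d[0, 1] == pytest.approx(1 / 3)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, size=(5, 8))
        x[:, 0] += 1  # no all-zero rows
        t = CountTable([f"s{i}" for i in range(5)], [f"o{j}" for j in range(8)], x)
        d = bray_curtis(t).d
        for i in range(5):
            for j in range(5):
                a, b = x[i].astype(float), x[j].astype(float)
                expect = 1 - 2 * np.minimum(a, b).sum() / (a.sum() + b.sum())
                assert d[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(d, d.T) and (d >= 0).all() and (d <= 1).all()


class TestHellinger:
    def test_uniform_row(self):
        t = CountTable(["a"], ["o1", "o2", "o3", "o4"], np.array([[1, 1, 1, 1]]))
        assert np.allclose(hellinger(t), 0.5)

    def test_rows_have_unit_squared_sum_and_zeros_stay(self):
        t = CountTable(
            ["a", "b"], ["o1", "o2", "o3"], np.array([[4, 0, 12], [1, 2, 3]])
        )
        h = hellinger(t)
        assert np.allclose((h**2).sum(axis=1), 1.0)
        assert h[0, 1] == 0.0


class TestNmds:
    def test_exactly_embeddable_recovers_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = DistanceMatrix([str(i) for i in range(6)], squareform(pdist(pts)))
        res = nmds(d, k=2, seed=0, n_restarts=8)
        assert res.stress < 1e-3

    def test_more_dimensions_never_worse(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 5))
        d = DistanceMatrix([str(i) for i in range(10)], squareform(pdist(pts)))
        s2 = nmds(d, k=2, seed=1, n_restarts=4).stress
        s3 = nmds(d, k=3, seed=1, n_restarts=4).stress
        assert s3 <= s2 + 1e-6

    def test_too_few_objects_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestMantel:
    def _dist(self, pts, ids=None):
        ids = ids or [str(i) for i in range(len(pts))]
        return DistanceMatrix(ids, squareform(pdist(pts)))

    def test_self_correlation_is_one(self):
        d = self._dist(np.random.default_rng(0).normal(size=(10, 3)))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_monotone_transform_spearman_invariant(self):
        d1 = self._dist(np.random.default_rng(1).normal(size=(8, 2)))
        d2 = DistanceMatrix(d1.ids, d1.d**2)  # monotone on distances
        assert mantel(d1, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_agrees_with_skbio_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        d1 = self._dist(rng.normal(size=(12, 3)))
        d2 = self._dist(rng.normal(size=(12, 3)), ids=d1.ids)
        ours = mantel(d1, d2, n_perm=99, seed=0).r
        theirs = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.d, ids=d1.ids),
            skbio_distance.DistanceMatrix(d2.d, ids=d2.ids),
            method="spearman",
            permutations=0,
        )[0]
        assert ours == pytest.approx(float(theirs), abs=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        # Kolmogorov-Smirnov sanity check on the permutation p-values
        from scipy.stats import kstest

        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            d1 = self._dist(rng.normal(size=(15, 3)))
            d2 = self._dist(rng.normal(size=(15, 3)), ids=d1.ids)
            pvals.append(mantel(d1, d2, n_perm=99, seed=rep).p)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_too_few_objects_rejected(self):
        d = self._dist(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError):
            mantel(d, d)


class TestDominantPhyla:
    def _fixture(self):
        # phylum shares: A 60%, B 30%, C exactly 1%, D 0.5%, rest E
        counts = np.array([[600, 300, 10, 5, 85]] * 3)
        t = CountTable(
            ["s1", "s2", "s3"], ["o1", "o2", "o3", "o4", "o5"], counts
        )
        tax = TaxonomyTable(
            {
                "o1": {"phylum": "Ascomycota"},
                "o2": {"phylum": "Basidiomycota"},
                "o3": {"phylum": "Chytridiomycota"},
                "o4": {"phylum": "Glomeromycota"},
                "o5": {"phylum": "Mortierellomycota"},
            }
        )
        return t, tax

    def test_strict_cutoff_excludes_exact_one_percent(self):
        t, tax = self._fixture()
        dom = dominant_phyla(t, tax)
        assert "Chytridiomycota" not in dom.index  # exactly 1.0%
        assert "Glomeromycota" not in dom.index  # 0.5%
        assert set(dom.index) == {
            "Ascomycota", "Basidiomycota", "Mortierellomycota"
        }

    def test_five_study_phyla_fixture(self):
        counts = np.array([[500, 250, 120, 80, 40, 10]] * 2)
        t = CountTable(
            ["s1", "s2"], [f"o{i}" for i in range(6)], counts
        )
        tax = TaxonomyTable(
            {
                "o0": {"phylum": "Ascomycota"},
                "o1": {"phylum": "Basidiomycota"},
                "o2": {"phylum": "Mortierellomycota"},
                "o3": {"phylum": "Glomeromycota"},
                "o4": {"phylum": "Chytridiomycota"},
                "o5": {"phylum": "Rozellomycota"},  # 1% exactly
            }
        )
        dom = dominant_phyla(t, tax)
        assert list(dom.index) == [
            "Ascomycota",
            "Basidiomycota",
            "Mortierellomycota",
            "Glomeromycota",
            "Chytridiomycota",
        ]

    def test_missing_phylum_goes_to_unassigned(self, small_table, small_taxonomy):
        dom = dominant_phyla(small_table, small_taxonomy)
        assert "Unassigned" in dom.index


class TestAlphaBundle:
    def test_invariants_on_random_tables(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 40, size=(6, 30)) + rng.integers(
            0, 2, size=(6, 30)
        )
        counts[:, 0] += 12  # avoid all-singleton degeneracy
        t = CountTable(
            [f"s{i}" for i in range(6)], [f"o{j}" for j in range(30)], counts
        )
        res = alpha_diversity(t).to_dataframe()
        assert (res["ace"] >= res["observed_otus"] - 1e-9).all()
        assert (res["shannon"] >= 0).all()
        assert (res["observed_otus"] <= 30).all()
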