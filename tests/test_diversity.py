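import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from micoval.diversity import (
    DistanceMatrix,
    anosim,
    beta_distance,
    fb_ratio,
    nmds,
    pcoa,
    shannon_index,
    simpson_index,
)
from micoval.io import FeatureTable, ValidationError


def dm_from(matrix, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return DistanceMatrix(pd.DataFrame(matrix, index=ids, columns=ids), metric="test")


def table_from(values, units="counts"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    data = pd.DataFrame(
        arr,
        index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )
    return FeatureTable(data, units=units)


class TestAlpha:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], np.log(4)),
            ([1.0], 0.0),
            ([0.5, 0.5, 0, 0], np.log(2)),
        ],
    )
    def test_shannon_closed_forms(self, vec, expected):
        assert shannon_index(np.array(vec)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "vec,expected",
        [([0.25] * 4, 0.75), ([1.0], 0.0), ([0.5, 0.5], 0.5)],
    )
    def test_simpson_closed_forms(self, vec, expected):
        assert simpson_index(np.array(vec)) == pytest.approx(expected, abs=1e-12)

    def test_shannon_maximal_iff_uniform(self):
        rng = np.random.default_rng(0)
        k = 6
        uniform = shannon_index(np.full(k, 1 / k))
        for _ in range(20):
            p = rng.dirichlet(np.ones(k))
            assert shannon_index(p) <= uniform + 1e-12

    def test_simpson_invariant_to_zero_padding(self):
        p = np.array([0.6, 0.4])
        padded = np.array([0.6, 0.4, 0.0, 0.0])
        assert simpson_index(p) == pytest.approx(simpson_index(padded))

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            shannon_index(np.zeros(3))


class TestFBRatio:
    def _phylum_table(self, f, b):
        data = pd.DataFrame(
            {"s1": [f, b, 0.1]},
            index=["Firmicutes", "Bacteroidetes", "Proteobacteria"],
        )
        return FeatureTable(data, units="relative", rank="phylum")

    def test_ratio_values(self):
        assert fb_ratio(self._phylum_table(0.6, 0.3))["s1"] == pytest.approx(2.0)
        assert fb_ratio(self._phylum_table(0.3, 0.3))["s1"] == pytest.approx(1.0)

    def test_zero_denominator_advises_imputation(self):
        with pytest.raises(ValidationError, match="impute"):
            fb_ratio(self._phylum_table(0.5, 0.0))

    def test_missing_phylum_row_rejected(self):
        table = table_from([[0.5], [0.5]])
        with pytest.raises(ValidationError, match="Firmicutes"):
            fb_ratio(table)

    def test_synonyms_not_matched(self):
        data = pd.DataFrame(
            {"s1": [0.5, 0.5]}, index=["Firmicutes", "Bacteroidota"]
        )
        with pytest.raises(ValidationError, match="Bacteroidetes"):
            fb_ratio(FeatureTable(data, units="relative"))


class TestBetaDistance:
    def test_identical_columns_are_zero(self):
        table = table_from([[0.3, 0.3], [0.7, 0.7]])
        for metric in ("bray_curtis", "jaccard"):
            assert beta_distance(table, metric).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_are_one(self):
        table = table_from([[1.0, 0.0], [0.0, 1.0]])
        for metric in ("bray_curtis", "jaccard"):
            assert beta_distance(table, metric).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_mixed_case(self):
        table = table_from([[1.0, 0.5], [0.0, 0.5]])
        assert beta_distance(table, "bray_curtis").values[0, 1] == pytest.approx(0.5)
        assert beta_distance(table, "jaccard").values[0, 1] == pytest.approx(0.5)

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        table = table_from(rng.random((20, 8)))
        for metric in ("bray_curtis", "jaccard"):
            vals = beta_distance(table, metric).values
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError):
            beta_distance(table_from([[1, 2]]), "unifrac")


class TestPCoA:
    def test_collinear_points_recover_unit_gaps(self):
        dm = dm_from([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(dm, k=1)
        axis = np.sort(res.coordinates["PCo1"].to_numpy())
        np.testing.assert_allclose(np.diff(axis), [1.0, 1.0], atol=1e-9)

    def test_two_samples_at_distance_d(self):
        res = pcoa(dm_from([[0, 3.5], [3.5, 0]]), k=1)
        coords = res.coordinates["PCo1"].to_numpy()
        assert abs(coords[0] - coords[1]) == pytest.approx(3.5, abs=1e-9)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(12, 2))
        dm = dm_from(squareform(pdist(points)))
        res = pcoa(dm, k=2)
        _, _, disparity = procrustes(points, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(10, 3))
        dm = dm_from(squareform(pdist(points)))
        res = pcoa(dm, k=3)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(rebuilt, dm.values, atol=1e-9)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        table = table_from(rng.random((15, 7)))
        dm = beta_distance(table, "bray_curtis")
        ours = pcoa(dm, k=2)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.values, ids=dm.sample_ids)
        )
        for axis in range(2):
            a = ours.coordinates.iloc[:, axis].to_numpy()
            b = ref.samples.iloc[:, axis].to_numpy()
            sign = np.sign(np.dot(a, b)) or 1.0
            np.testing.assert_allclose(a, sign * b, atol=1e-8)


class TestNMDS:
    def _euclidean_dm(self, n=8, seed=5):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(n, 2))
        return dm_from(squareform(pdist(points)))

    def test_representable_configuration_has_low_stress(self):
        res = nmds(self._euclidean_dm(), k=2, restarts=8, seed=0)
        assert res.stress < 0.01

    def test_seed_determinism(self):
        dm = self._euclidean_dm()
        a = nmds(dm, k=2, restarts=4, seed=3)
        b = nmds(dm, k=2, restarts=4, seed=3)
        assert a.stress == b.stress
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)

    def test_stress_bounded_and_non_increasing_with_iterations(self):
        rng = np.random.default_rng(9)
        table = table_from(rng.random((25, 8)))
        dm = beta_distance(table, "bray_curtis")
        stresses = [
            nmds(dm, k=2, restarts=1, seed=1, max_iter=it).stress
            for it in (5, 30, 300)
        ]
        assert all(0 <= s <= 1 for s in stresses)
        assert stresses[0] >= stresses[1] >= stresses[2] - 1e-12


class TestANOSIM:
    def test_complete_separation_gives_r_one(self):
        within, between = 0.1, 0.9
        n = 6
        mat = np.full((n, n), between)
        mat[:3, :3] = within
        mat[3:, 3:] = within
        np.fill_diagonal(mat, 0.0)
        res = anosim(dm_from(mat), ["a"] * 3 + ["b"] * 3, permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 10, abs=0.05)

    def test_duplicated_points_give_nonpositive_r(self):
        mat = np.zeros((6, 6))
        res = anosim(dm_from(mat), ["a"] * 3 + ["b"] * 3, permutations=99, seed=0)
        assert res.r <= 0

    def test_statistic_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(21)
        table = table_from(rng.random((30, 12)))
        dm = beta_distance(table, "bray_curtis")
        labels = ["a"] * 6 + ["b"] * 6
        ours = anosim(dm, labels, permutations=99, seed=0)
        ref = sk_anosim(
            skbio.DistanceMatrix(dm.values, ids=dm.sample_ids),
            grouping=labels,
            permutations=0,
        )
        assert ours.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            anosim(dm_from(np.zeros((3, 3))), ["a", "a", "b"])

    def test_p_super_uniform_under_label_exchange(self):
        # with random labels, P(p <= 0.05) should not exceed ~alpha
        rng = np.random.default_rng(4)
        hits = 0
        reps = 100
        for _ in range(reps):
            pts = rng.normal(size=(10, 3))
            dm = dm_from(squareform(pdist(pts)))
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            res = anosim(dm, labels, permutations=99, seed=int(rng.integers(2**31)))
            hits += res.p <= 0.05
        assert hits / reps <= 0.12
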