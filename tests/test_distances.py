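import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microgeo as mg


class TestKLDivergence:
    def test_identity_is_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert mg.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_no_smoothing(self):
        val = mg.kl_divergence([0.5, 0.5], [0.25, 0.75], pseudocount=0)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.14384, abs=1e-5)

    def test_zero_in_q_finite_with_smoothing(self):
        val = mg.kl_divergence([0.5, 0.5], [1.0, 0.0], pseudocount=1e-6)
        assert np.isfinite(val) and val > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mg.kl_divergence([0.5, 0.5], [1.0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_on_random_compositions(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        assert mg.kl_divergence(p, q) >= 0.0
        assert mg.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def labelled_relative():
    cfg = mg.SyntheticConfig(n_cities=3, samples_per_city=(8, 8, 8), n_taxa=80,
                             n_signature_taxa_per_city=6, confusable_pairs=(),
                             signature_log_fold=3.0, seed=21)
    table, _ = mg.generate_dataset(cfg)
    return mg.filter_and_renormalize(table)


class TestKLPredict:
    def test_identical_training_sample_wins(self, labelled_relative):
        rel = labelled_relative
        ranked = mg.kl_predict(rel.values[0], rel, top_m=1)
        assert ranked == [rel.labels[0]]

    def test_top_m_all_cities_is_permutation(self, labelled_relative):
        rel = labelled_relative
        cities = sorted(set(rel.labels))
        ranked = mg.kl_predict(rel.values[5], rel, top_m=len(cities))
        assert sorted(ranked) == cities

    def test_top3_contains_top1(self, labelled_relative):
        rel = labelled_relative
        for row in rel.values[:10]:
            top1 = mg.kl_predict(row, rel, top_m=1)
            top3 = mg.kl_predict(row, rel, top_m=3)
            assert top1[0] == top3[0]
            assert top1[0] in top3

    def test_city_mean_mode_runs(self, labelled_relative):
        rel = labelled_relative
        ranked = mg.kl_predict(rel.values[0], rel, top_m=2, aggregate="mean")
        assert len(ranked) == 2

    def test_unlabelled_training_rejected(self, labelled_relative):
        rel = labelled_relative
        bare = mg.LabeledAbundanceTable(rel.sample_ids, rel.taxon_ids, rel.lineages,
                                        rel.values, mode="relative")
        with pytest.raises(ValueError):
            mg.kl_predict(rel.values[0], bare)


class TestEcologicalDistance:
    def test_kulczynski_identity(self):
        x = np.array([1.0, 2.0, 3.0, 0.0])
        assert mg.ecological_distance(x, x) == pytest.approx(0.0)

    def test_kulczynski_worked_example(self):
        # presence {0,1,2} vs {1,2,3}: a=2, b=1, c=1 -> 1 - (2/3 + 2/3)/2 = 1/3
        x = np.array([1.0, 1.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 1.0, 1.0])
        assert mg.ecological_distance(x, y) == pytest.approx(1 / 3)

    def test_disjoint_presence_is_one(self):
        assert mg.ecological_distance([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_empty_sample_undefined(self):
        with pytest.raises(ValueError):
            mg.ecological_distance([0, 0], [1, 1])

    def test_bray_curtis_matches_formula(self):
        x, y = np.array([2.0, 1.0]), np.array([1.0, 3.0])
        assert mg.ecological_distance(x, y, "bray_curtis") == pytest.approx(3 / 7)

    @pytest.mark.parametrize("method", ["kulczynski_qualitative", "bray_curtis"])
    def test_symmetry_and_range(self, method):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random(10) * (rng.random(10) > 0.3)
            y = rng.random(10) * (rng.random(10) > 0.3)
            if not x.any() or not y.any():
                continue
            d_xy = mg.ecological_distance(x, y, method)
            d_yx = mg.ecological_distance(y, x, method)
            assert d_xy == pytest.approx(d_yx)
            assert 0.0 <= d_xy <= 1.0


def separated_matrix():
    """2 cities x 3 samples; within-city < between-city distances."""
    ids = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    d = np.full((6, 6), 5.0)
    d[:3, :3] = 1.0
    d[3:, 3:] = 1.0
    np.fill_diagonal(d, 0.0)
    labels = {s: ("A" if s.startswith("a") else "B") for s in ids}
    return mg.DistanceMatrix(ids, d), labels


class TestAverageDistancePredict:
    def test_constructed_metric_gives_perfect_loocv(self):
        dm, labels = separated_matrix()
        assert mg.loocv_accuracy(dm, labels) == 1.0

    def test_loocv_excludes_self_distance(self):
        # without exclusion the query's own zero would drag its city mean down
        ids = ["q", "x1", "y1", "y2"]
        d = np.array([[0.0, 9.0, 4.0, 4.0],
                      [9.0, 0.0, 9.0, 9.0],
                      [4.0, 9.0, 0.0, 1.0],
                      [4.0, 9.0, 1.0, 0.0]])
        dm = mg.DistanceMatrix(ids, d)
        labels = {"q": "X", "x1": "X", "y1": "Y", "y2": "Y"}
        preds = mg.average_distance_predict(dm, labels, ["q"], loocv=True)
        assert preds["q"] == "Y"  # mean to X is 9 once self is excluded

    def test_forced_argmin_singleton_cities(self):
        ids = ["q", "near", "far"]
        d = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        dm = mg.DistanceMatrix(ids, d)
        preds = mg.average_distance_predict(dm, {"near": "N", "far": "F"}, ["q"])
        assert preds["q"] == "N"

    def test_invariant_to_constant_offset(self):
        dm, labels = separated_matrix()
        shifted = dm.values + 2.0
        np.fill_diagonal(shifted, 0.0)
        dm2 = mg.DistanceMatrix(dm.ids, shifted)
        p1 = mg.average_distance_predict(dm, labels, list(labels), loocv=True)
        p2 = mg.average_distance_predict(dm2, labels, list(labels), loocv=True)
        assert p1 == p2

    def test_unknown_query_rejected(self):
        dm, labels = separated_matrix()
        with pytest.raises(ValueError):
            mg.average_distance_predict(dm, labels, ["nope"])


class TestDistanceMatrix:
    def test_tsv_roundtrip(self, tmp_path):
        dm, _ = separated_matrix()
        dm.to_tsv(tmp_path / "d.tsv")
        back = mg.DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.ids == dm.ids
        np.testing.assert_allclose(back.values, dm.values)

    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            mg.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_pairwise_from_table(self, labelled_relative):
        dm = mg.pairwise_distances(labelled_relative.subset_samples(range(6)))
        assert np.allclose(np.diag(dm.values), 0.0)
        assert np.allclose(dm.values, dm.values.T)
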