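import numpy as np
import pytest

import microgeo as mg
from microgeo.ensemble import FittedCandidate


@pytest.fixture(scope="module")
def fitted_small(default_relative):
    """One small ensemble on the reference data, shared across tests."""
    rel, truth = default_relative
    y = rel.label_array()
    tr, te = mg.stratified_holdout(y, 0.8, 3, seed=1)
    roster = [c for c in mg.standard_roster() if c.id in ("rf", "rpart")]
    model = mg.fit_ensemble(
        rel.subset_samples(tr),
        mg.EnsembleConfig(roster=roster, n_bootstraps=5, seed=1),
    )
    return model, rel, tr, te


class TestStratifiedBootstrap:
    def test_contract_all_classes_in_bag(self):
        labels = ["a", "a", "b", "b", "c", "c"]
        in_bag, oob = mg.stratified_bootstrap(labels, seed=0)
        assert len(in_bag) == 6
        assert {labels[i] for i in in_bag} == {"a", "b", "c"}
        assert set(oob) == set(range(6)) - set(in_bag)

    def test_same_seed_same_draw(self):
        labels = ["a"] * 5 + ["b"] * 5
        d1 = mg.stratified_bootstrap(labels, seed=7)
        d2 = mg.stratified_bootstrap(labels, seed=7)
        np.testing.assert_array_equal(d1[0], d2[0])
        np.testing.assert_array_equal(d1[1], d2[1])

    def test_mean_oob_fraction_matches_closed_form(self):
        # E[|OOB|/n] = (1 - 1/n)^n ~ 0.364 at n = 50
        labels = ["a"] * 25 + ["b"] * 25
        fracs = [len(mg.stratified_bootstrap(labels, seed=s)[1]) / 50
                 for s in range(1000)]
        assert np.mean(fracs) == pytest.approx((1 - 1 / 50) ** 50, abs=0.02)

    def test_pathological_data_errors(self):
        with pytest.raises(ValueError):
            mg.stratified_bootstrap(["a", "b"], seed=0, max_retries=3)


class TestFitEnsemble:
    def test_single_candidate_roster_wins_everything(self, default_relative):
        rel, _ = default_relative
        roster = [c for c in mg.standard_roster() if c.id == "rpart"]
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(roster=roster, n_bootstraps=4, seed=0))
        assert model.winner_ids == ["rpart"] * 4
        assert model.winner_counts == {"rpart": 4}

    def test_single_bootstrap_equals_winner(self, default_relative):
        rel, _ = default_relative
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(
            roster=mg.standard_roster()[:3], n_bootstraps=1, seed=2))
        preds = mg.predict_majority(model, rel.values)
        np.testing.assert_array_equal(preds, model.winners[0].predict(rel.values))

    def test_winner_counts_sum_to_n(self, fitted_small):
        model, *_ = fitted_small
        assert sum(model.winner_counts.values()) == model.n_bootstraps
        assert len(model.oob_reports) == model.n_bootstraps

    def test_input_table_never_mutated(self, default_relative):
        rel, _ = default_relative
        before = rel.values.copy()
        mg.fit_ensemble(rel, mg.EnsembleConfig(
            roster=mg.standard_roster()[:2], n_bootstraps=2,
            imbalance_mode="oversample", seed=3))
        np.testing.assert_array_equal(rel.values, before)

    def test_feature_mismatch_rejected(self, fitted_small):
        model, rel, *_ = fitted_small
        with pytest.raises(ValueError):
            mg.predict_majority(model, rel.values[:, :10])

    def test_determinism_of_winners_and_predictions(self, default_relative):
        rel, _ = default_relative
        cfg = dict(roster=mg.standard_roster()[:3], n_bootstraps=3, seed=9)
        m1 = mg.fit_ensemble(rel, mg.EnsembleConfig(**cfg))
        m2 = mg.fit_ensemble(rel, mg.EnsembleConfig(**cfg))
        assert m1.winner_ids == m2.winner_ids
        np.testing.assert_array_equal(
            mg.predict_majority(m1, rel.values), mg.predict_majority(m2, rel.values)
        )


class _StubWinner:
    def __init__(self, label):
        self.label = label
        self.projection = None
        self.estimator = None

    def predict(self, X):
        return np.full(len(X), self.label, dtype=object)


def make_stub_model(vote_labels, class_counts):
    classes = sorted(class_counts)
    return mg.EnsembleModel(
        winners=[_StubWinner(l) for l in vote_labels],
        winner_ids=["stub"] * len(vote_labels),
        winner_counts={"stub": len(vote_labels)},
        oob_reports=[],
        classes=classes,
        class_counts=class_counts,
        feature_names=None,
    )


class TestMajorityVote:
    def test_strict_majority(self):
        model = make_stub_model(["A", "A", "B"], {"A": 5, "B": 5})
        assert mg.predict_majority(model, np.zeros((2, 3)))[0] == "A"

    def test_unanimity(self):
        model = make_stub_model(["B", "B", "B"], {"A": 5, "B": 5})
        assert mg.predict_majority(model, np.zeros((1, 3)))[0] == "B"

    def test_tie_broken_by_training_frequency(self):
        model = make_stub_model(["A", "B"], {"A": 50, "B": 10})
        assert mg.predict_majority(model, np.zeros((1, 3)))[0] == "A"

    def test_tie_broken_lexicographically_when_counts_equal(self):
        model = make_stub_model(["B", "A"], {"A": 10, "B": 10})
        assert mg.predict_majority(model, np.zeros((1, 3)))[0] == "A"

    def test_vote_fractions_rows_sum_to_one(self, fitted_small):
        model, rel, _, te = fitted_small
        frac = mg.vote_fractions(model, rel.values[te])
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)


class TestFeatureImportance:
    def test_single_forest_winner_returns_its_vector(self, default_relative):
        rel, _ = default_relative
        roster = [c for c in mg.standard_roster() if c.id == "rf"]
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(roster=roster, n_bootstraps=1, seed=4))
        imp = mg.rf_feature_importance(model, top_k=5)
        assert len(imp) == 5
        own = model.winners[0].estimator.feature_importances_
        top = np.argsort(own)[::-1][:5]
        assert list(imp["taxon_id"]) == [model.feature_names[i] for i in top]

    def test_importances_normalised_per_forest(self, default_relative):
        rel, _ = default_relative
        roster = [c for c in mg.standard_roster() if c.id == "rf"]
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(roster=roster, n_bootstraps=2, seed=5))
        for w in model.winners:
            assert w.estimator.feature_importances_.sum() == pytest.approx(1.0)

    def test_no_forest_winner_returns_empty(self, default_relative):
        rel, _ = default_relative
        roster = [c for c in mg.standard_roster() if c.id == "rpart"]
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(roster=roster, n_bootstraps=1, seed=6))
        assert mg.rf_feature_importance(model).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_signatures_recovered(self, seed):
        """At least 60% of planted signature taxa rank in the top 2x slots."""
        cfg = mg.SyntheticConfig(seed=500 + seed)
        table, truth = mg.generate_dataset(cfg)
        rel = mg.filter_and_renormalize(table)
        roster = [c for c in mg.standard_roster() if c.id == "rf"]
        model = mg.fit_ensemble(rel, mg.EnsembleConfig(roster=roster, n_bootstraps=3,
                                                       seed=seed))
        planted = {f"s__taxon{i:05d}" for i in truth.all_signature_indices()}
        planted &= set(rel.taxon_ids)  # filtering may drop a few
        top = set(mg.rf_feature_importance(model, top_k=2 * len(planted))["taxon_id"])
        assert len(planted & top) / len(planted) >= 0.6


class TestRepeatedStudy:
    def test_degenerate_study_reduces_to_single_evaluation(self, default_relative):
        rel, _ = default_relative
        roster = [c for c in mg.standard_roster() if c.id == "rpart"]
        cfg = mg.EnsembleConfig(roster=roster, n_bootstraps=1, seed=7)
        report = mg.run_repeated_study(rel, cfg, n_repeats=1, seed=7)
        assert set(report.summary["classifier"]) == {"ensemble", "rpart"}
        assert sum(report.winner_counts["standard"].values()) == 1

    def test_winner_counts_accounting(self, default_relative, tiny_roster):
        rel, _ = default_relative
        cfg = mg.EnsembleConfig(roster=tiny_roster, n_bootstraps=3, seed=8)
        report = mg.run_repeated_study(rel, cfg, n_repeats=2, seed=8)
        assert sum(report.winner_counts["standard"].values()) == 2 * 3

    def test_split_respects_min_per_city(self, default_relative):
        rel, _ = default_relative
        y = rel.label_array()
        tr, te = mg.stratified_holdout(y, 0.8, 3, seed=0)
        for c in set(y):
            assert np.sum(y[tr] == c) >= 3
            assert np.sum(y[te] == c) >= 3
        assert set(tr) & set(te) == set()

    def test_infeasible_split_errors(self):
        with pytest.raises(ValueError):
            mg.stratified_holdout(["a"] * 4 + ["b"] * 20, 0.8, 3, seed=0)
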