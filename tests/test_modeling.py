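"""Site classifier, LOGO evaluation, PLS benchmark, ridge ensemble."""

import numpy as np
import pytest

from redoxscreen import modeling as mdl
from redoxscreen.qm_features import AtomFeatureVector


def make_atom(mol_id, idx, f0, oxidized, group):
    import zlib

    values = np.zeros(34)
    values[0] = f0
    rng = np.random.default_rng(zlib.crc32(f"{mol_id}:{idx}".encode()))
    values[1:] = rng.normal(0, 0.1, 33)
    return mdl.SiteLabeledAtom(mol_id, idx, AtomFeatureVector(values, idx,
                                                              mol_id),
                               oxidized, group)


@pytest.fixture(scope="module")
def planted_site_data():
    """500 atoms where oxidized <=> f0 > 0, across 5 template groups."""
    rng = np.random.default_rng(42)
    atoms = []
    for m in range(100):
        group = f"T{m % 5 + 1}"
        for i in range(5):
            f0 = float(rng.normal())
            atoms.append(make_atom(f"m{m}", i, f0, f0 > 0, group))
    return atoms


class TestSiteClassifier:
    def test_recovers_planted_rule(self, planted_site_data):
        train, test = planted_site_data[:400], planted_site_data[400:]
        clf = mdl.train_site_classifier(train)
        X = np.vstack([a.features.values for a in test])
        y = np.array([int(a.oxidized) for a in test])
        acc = np.mean(clf.predict(X) == y)
        assert acc >= 0.95

    def test_probabilities_deterministic_on_repeat(self, planted_site_data):
        clf = mdl.train_site_classifier(planted_site_data)
        x = planted_site_data[0].features.values[None, :]
        assert clf.predict_proba(x)[0] == clf.predict_proba(x)[0]

    def test_probabilities_rank_sites_within_molecule(self,
                                                      planted_site_data):
        """Per-atom probabilities order candidate sites by f0."""
        clf = mdl.train_site_classifier(planted_site_data)
        feats = [make_atom("q", i, f0, False, "T1").features.values
                 for i, f0 in enumerate([-2.0, 0.1, 2.0])]
        probs = clf.predict_proba(np.vstack(feats))
        assert probs[2] == max(probs)
        assert probs[0] == min(probs)

    def test_single_class_input_raises(self):
        atoms = [make_atom("m", i, 1.0, True, "T1") for i in range(10)]
        with pytest.raises(mdl.ModelingError, match="single class"):
            mdl.train_site_classifier(atoms)


class TestLogo:
    def test_five_groups_give_five_single_group_folds(self,
                                                      planted_site_data):
        report = mdl.evaluate_logo(planted_site_data)
        assert report.n_folds == 5
        assert sorted(f.held_out_group for f in report.folds) == [
            "T1", "T2", "T3", "T4", "T5"]

    def test_perfect_classifier_on_separable_data(self, planted_site_data):
        """With a noiseless planted rule the aggregate scores reach 1."""
        report = mdl.evaluate_logo(planted_site_data)
        assert report.aggregate_precision >= 0.95
        assert report.aggregate_recall >= 0.95

    def test_aggregate_equals_hand_pooled_counts(self):
        """Pooled precision/recall on a 30-atom fixture, exactly."""
        rng = np.random.default_rng(7)
        atoms = []
        for m in range(10):
            group = f"T{m % 3 + 1}"
            for i in range(3):
                f0 = float(rng.normal())
                atoms.append(make_atom(f"m{m}", i, f0, f0 > 0.2, group))
        report = mdl.evaluate_logo(atoms)
        tp = sum(f.tp for f in report.folds)
        fp = sum(f.fp for f in report.folds)
        fn = sum(f.fn for f in report.folds)
        tn = sum(f.tn for f in report.folds)
        assert tp + fp + fn + tn == 30
        expected_p = tp / (tp + fp) if tp + fp else 0.0
        expected_r = tp / (tp + fn) if tp + fn else 0.0
        assert report.aggregate_precision == expected_p
        assert report.aggregate_recall == expected_r

    def test_single_class_training_fold_skipped_with_warning(self, caplog):
        # all positives live in group T1: its fold trains on negatives only
        atoms = [make_atom(f"p{i}", 0, 1.0, True, "T1") for i in range(5)]
        atoms += [make_atom(f"n{i}", 0, -1.0, False, f"T{2 + i % 2}")
                  for i in range(10)]
        with caplog.at_level("WARNING"):
            report = mdl.evaluate_logo(atoms)
        skipped = [f for f in report.folds if f.skipped]
        assert [f.held_out_group for f in skipped] == ["T1"]
        assert "single-class" in caplog.text

    def test_fewer_than_two_groups_rejected(self):
        atoms = [make_atom(f"m{i}", 0, float(i - 2), i > 2, "T1")
                 for i in range(6)]
        with pytest.raises(mdl.ModelingError, match="2 template groups"):
            mdl.evaluate_logo(atoms)


class TestRegressionBenchmark:
    def test_noiseless_linear_target_gives_unit_r2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 8))
        beta = rng.normal(size=8)
        y = X @ beta
        report = mdl.train_regression_benchmark(
            X, y, mdl.RegressionConfig(n_components=8, seed=1))
        assert all(abs(r2 - 1.0) < 1e-6 for r2 in report.r2_per_split)

    def test_permuted_labels_have_no_skill(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 10))
        y = X @ rng.normal(size=10)
        null_r2 = []
        for k in range(20):
            y_perm = np.random.default_rng(k).permutation(y)
            rep = mdl.train_regression_benchmark(
                X, y_perm, mdl.RegressionConfig(n_components=3, seed=k))
            null_r2.append(rep.mean_r2)
        assert np.mean(null_r2) <= 0.1

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.raises(mdl.ModelingError, match="constant"):
            mdl.train_regression_benchmark(X, np.ones(20))

    def test_compare_representations_shares_splits(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.1, 40)
        reports = mdl.compare_representations(
            {"a": X, "b": X}, y, mdl.RegressionConfig(n_components=4, seed=2))
        assert reports["a"].r2_per_split == reports["b"].r2_per_split


@pytest.fixture(scope="module")
def competency_records():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(141, 16))
    w = rng.normal(size=16)
    y = np.where(X @ w > 0, 1, -1)
    return [mdl.CompetencyRecord(f"c{i:03d}", X[i], int(y[i]))
            for i in range(141)]


class TestEnsemble:
    def test_canonical_split_is_116_25_disjoint_exhaustive(
            self, competency_records):
        model = mdl.train_reactivity_ensemble(
            competency_records, mdl.EnsembleConfig(seed=0))
        all_ids = {r.molecule_id for r in competency_records}
        for train_ids, test_ids in model.member_splits:
            assert len(train_ids) == 116
            assert len(test_ids) == 25
            assert set(train_ids) | set(test_ids) == all_ids
            assert not set(train_ids) & set(test_ids)

    def test_default_has_exactly_ten_members(self, competency_records):
        model = mdl.train_reactivity_ensemble(
            competency_records, mdl.EnsembleConfig(seed=1))
        assert len(model.members) == 10
        assert len(model.member_accuracies) == 10

    def test_fixed_seed_reproduces_splits_and_accuracy(
            self, competency_records):
        a = mdl.train_reactivity_ensemble(competency_records,
                                          mdl.EnsembleConfig(seed=5))
        b = mdl.train_reactivity_ensemble(competency_records,
                                          mdl.EnsembleConfig(seed=5))
        assert a.member_splits == b.member_splits
        assert a.mean_accuracy == b.mean_accuracy

    def test_split_ratio_scales_for_other_sizes(self, competency_records):
        model = mdl.train_reactivity_ensemble(
            competency_records[:100], mdl.EnsembleConfig(seed=2))
        train_ids, test_ids = model.member_splits[0]
        assert len(train_ids) == round(116 / 141 * 100)  # = 82
        assert len(test_ids) == 100 - len(train_ids)

    def test_planted_linear_rule_recovered(self, competency_records):
        model = mdl.train_reactivity_ensemble(
            competency_records, mdl.EnsembleConfig(seed=3))
        assert model.mean_accuracy >= 0.9

    def test_too_small_dataset_rejected(self, competency_records):
        with pytest.raises(mdl.ModelingError):
            mdl.train_reactivity_ensemble(competency_records[:10])

    def test_single_class_dataset_rejected(self):
        rng = np.random.default_rng(0)
        recs = [mdl.CompetencyRecord(f"r{i}", rng.normal(size=4), 1)
                for i in range(30)]
        with pytest.raises(mdl.ModelingError, match="single class"):
            mdl.train_reactivity_ensemble(recs)

    def test_save_load_predicts_identically(self, competency_records,
                                            tmp_path):
        model = mdl.train_reactivity_ensemble(
            competency_records, mdl.EnsembleConfig(seed=4))
        path = tmp_path / "ens.json"
        model.save(str(path))
        loaded = mdl.EnsembleModel.load(str(path))
        X = np.vstack([r.vector for r in competency_records[:7]])
        np.testing.assert_array_equal(model.votes(X), loaded.votes(X))


class TestEnsemblePredict:
    @staticmethod
    def forced_model(votes):
        """Ensemble whose members deterministically emit given +/-1 votes."""

        class FixedMember:
            n_features_in_ = 3

            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        cfg = mdl.EnsembleConfig()
        return mdl.EnsembleModel([FixedMember(v) for v in votes],
                                 [([], [])] * len(votes),
                                 [1.0] * len(votes), cfg)

    def test_unanimous_positive(self):
        model = self.forced_model([1] * 10)
        label, prob, mean_vote = mdl.ensemble_predict(model, np.zeros(3))
        assert (label, prob, mean_vote) == (1, 1.0, 1.0)

    def test_six_of_ten_positive(self):
        model = self.forced_model([1] * 6 + [-1] * 4)
        label, prob, mean_vote = mdl.ensemble_predict(model, np.zeros(3))
        assert label == 1
        assert prob == pytest.approx(0.6)
        assert mean_vote == pytest.approx(0.2)

    def test_tie_vote_classified_negative(self):
        model = self.forced_model([1] * 5 + [-1] * 5)
        label, prob, mean_vote = mdl.ensemble_predict(model, np.zeros(3))
        assert label == -1
        assert mean_vote == 0.0

    def test_probability_is_k_tenths_and_monotone(self):
        probs = []
        for k in range(11):
            model = self.forced_model([1] * k + [-1] * (10 - k))
            _, prob, _ = mdl.ensemble_predict(model, np.zeros(3))
            assert prob == pytest.approx(k / 10)
            probs.append(prob)
        assert probs == sorted(probs)

    def test_dimension_mismatch_raises(self, competency_records):
        model = mdl.train_reactivity_ensemble(
            competency_records, mdl.EnsembleConfig(seed=6))
        with pytest.raises(mdl.ModelingError, match="dimension"):
            mdl.ensemble_predict(model, np.zeros(5))
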