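"""Splitting, hyperparameter selection, per-length model training/persistence."""

import numpy as np
import pytest

from plantdti import (
    ModelRegistry, predict_proba, roc_auc, select_knn_k, split_train_test,
    train_length_model, train_suite,
)
from plantdti.errors import (
    ConfigurationError, KeyMismatchError, StratificationError, TrainingError,
)
from plantdti.evaluation import evaluate
from plantdti.feature_encoding import BINARY
from plantdti.io_tables import InteractionRecord
from plantdti.synthetic_data import benchmark_config, sample_catalogue


def _records(n_pos, n_neg, length=7, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_pos + n_neg):
        seq = "".join(rng.choice(list("ACGT"), length))
        label = 1 if i < n_pos else 0
        recs.append(InteractionRecord(f"tf{i}", "D1", "RKHSNQDE", seq, label=label))
    return recs


class TestSplit:
    def test_70_30_arithmetic_on_balanced_records(self):
        records = _records(500, 500)
        train, test = split_train_test(records, ratio=0.70, seed=0)
        assert (len(train), len(test)) == (700, 300)
        assert sum(r.label for r in train) == 350
        assert sum(r.label for r in test) == 150

    def test_partitions_disjoint_and_exhaustive(self):
        records = _records(40, 60)
        train, test = split_train_test(records, seed=1)
        ids = {r.tf_id for r in records}
        assert {r.tf_id for r in train} | {r.tf_id for r in test} == ids
        assert {r.tf_id for r in train} & {r.tf_id for r in test} == set()

    def test_seed_reproducible(self):
        records = _records(30, 30)
        assert split_train_test(records, seed=5) == split_train_test(records, seed=5)

    def test_degenerate_ratios_rejected(self):
        records = _records(10, 10)
        with pytest.raises(ConfigurationError):
            split_train_test(records, ratio=1.0)
        with pytest.raises(ConfigurationError):
            split_train_test(records, ratio=0.0)

    def test_tiny_stratum_rejected(self):
        records = _records(1, 10)
        with pytest.raises(StratificationError):
            split_train_test(records)


class TestSelectKnnK:
    def _clouds(self, seed=0, n=60, sep=8.0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n, 5)), rng.normal(sep, 1, (n, 5))])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separated_clouds_tie_break_to_smallest_k(self):
        X, y = self._clouds()
        best_k, table = select_knn_k(X, y, k_grid=(3, 5, 7, 9, 11), seed=0)
        assert best_k == 3
        assert all(f1 == pytest.approx(1.0) for _, f1 in table)

    def test_singleton_grid(self):
        X, y = self._clouds()
        best_k, _ = select_knn_k(X, y, k_grid=(5,), seed=0)
        assert best_k == 5

    def test_permuted_labels_near_chance(self):
        X, y = self._clouds(n=100)
        rng = np.random.default_rng(1)
        best_k, table = select_knn_k(X, rng.permutation(y), k_grid=(3, 11, 21), seed=0)
        for _, f1 in table:
            assert 0.3 < f1 < 0.7

    def test_too_small_class_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 6 + [1] * 6)
        with pytest.raises(TrainingError):
            select_knn_k(X, y, folds=10)


@pytest.fixture(scope="module")
def mini_length7(mini_benchmark):
    """Positive + RP negative records of length 7 from the small catalogue."""
    from plantdti import generate_rp

    positives = [p for p in mini_benchmark.positives if p.length == 7]
    negatives = generate_rp(positives, seed=0).records
    return positives + negatives


class TestTrainLengthModel:
    def test_separable_training_data_refit_scores_high(self, mini_length7):
        train, _ = split_train_test(mini_length7, seed=0)
        model = train_length_model(train, 7, "RP", seed=0)
        results = predict_proba(model, train)
        metrics = evaluate([(r.label, p.prob) for r, p in zip(train, results)],
                           threshold=0.5)
        assert metrics.f1 >= 0.99

    def test_shuffled_labels_give_chance_auroc(self):
        config = benchmark_config(seed=11, lengths=(7,), tfs_per_type=300,
                                  motifs_per_type=300, planting_strength=0.5)
        positives = sample_catalogue(config).positives()
        from plantdti import generate_rp

        records = positives + generate_rp(positives, seed=11).records
        rng = np.random.default_rng(11)
        labels = rng.permutation([r.label for r in records])
        shuffled = [
            InteractionRecord(r.tf_id, r.dbd_type, r.dbd_sequence, r.tfbs_sequence,
                              label=int(l), source=r.source)
            for r, l in zip(records, labels)
        ]
        train, test = split_train_test(shuffled, seed=11)
        model = train_length_model(train, 7, "RP", seed=11)
        results = predict_proba(model, test)
        auroc, _ = roc_auc([(r.label, p.prob) for r, p in zip(test, results)])
        assert auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        records = _records(10, 0)
        with pytest.raises(TrainingError):
            train_length_model(records, 7, "RP")

    def test_wrong_length_rejected(self, mini_length7):
        with pytest.raises(KeyMismatchError):
            train_length_model(mini_length7, 9, "RP")

    @pytest.mark.parametrize("classifier", ["NB", "KNN"])
    def test_alternative_classifiers_fit_and_predict(self, mini_length7, classifier):
        train, test = split_train_test(mini_length7, seed=2)
        model = train_length_model(train, 7, "RP", classifier=classifier,
                                   seed=2, knn_grid=(3, 5))
        results = predict_proba(model, test)
        assert all(0 <= r.prob <= 1 for r in results)


class TestPredict:
    def test_empty_pairs(self, mini_registry):
        assert predict_proba(mini_registry.get(7, "RP"), []) == []

    def test_order_invariance(self, mini_registry, mini_benchmark):
        pairs = [p for p in mini_benchmark.positives if p.length == 7][:10]
        model = mini_registry.get(7, "RP")
        fwd = predict_proba(model, pairs)
        rev = predict_proba(model, pairs[::-1])
        assert {(r.tf_id, r.tfbs_sequence, r.prob) for r in fwd} == \
               {(r.tf_id, r.tfbs_sequence, r.prob) for r in rev}

    def test_length_mismatch_rejected(self, mini_registry, mini_benchmark):
        pairs = [p for p in mini_benchmark.positives if p.length == 9]
        with pytest.raises(KeyMismatchError):
            predict_proba(mini_registry.get(7, "RP"), pairs[:1])

    def test_heavily_represented_positive_scores_high(self, mini_registry, mini_benchmark):
        pairs = [p for p in mini_benchmark.positives if p.length == 7][:5]
        results = predict_proba(mini_registry.get(7, "RP"), pairs)
        assert all(r.prob > 0.5 for r in results)


class TestSuiteAndPersistence:
    def test_two_lengths_give_four_models(self, mini_registry):
        assert len(mini_registry.models) == 4
        assert mini_registry.lengths == [7, 9]
        assert {s for _, s in mini_registry.models} == {"RP", "RW"}

    def test_manifest_records_provenance(self, mini_registry):
        assert mini_registry.manifest["classifier"] == "RF"
        assert mini_registry.manifest["seed"] == 3
        for model in mini_registry.models.values():
            assert model.hyperparams == {"n_trees": 100}
            assert model.fitted

    def test_round_trip_probabilities_bit_identical(self, tmp_path, mini_registry,
                                                    mini_benchmark):
        mini_registry.save(tmp_path / "models")
        loaded = ModelRegistry.load(tmp_path / "models")
        pairs = [p for p in mini_benchmark.positives if p.length == 9][:20]
        before = predict_proba(mini_registry.get(9, "RW"), pairs)
        after = predict_proba(loaded.get(9, "RW"), pairs)
        assert [r.prob for r in before] == [r.prob for r in after]
        assert loaded.metrics.keys() == mini_registry.metrics.keys()

    def test_retraining_with_same_seed_reproduces_probabilities(self, mini_benchmark,
                                                                mini_registry):
        again = train_suite(mini_benchmark.positives, seed=3)
        pairs = [p for p in mini_benchmark.positives if p.length == 7][:20]
        a = predict_proba(mini_registry.get(7, "RP"), pairs)
        b = predict_proba(again.get(7, "RP"), pairs)
        assert [r.prob for r in a] == [r.prob for r in b]
        for key in mini_registry.metrics:
            assert mini_registry.metrics[key] == again.metrics[key]

    def test_missing_model_is_configuration_error(self, mini_registry):
        with pytest.raises(ConfigurationError):
            mini_registry.get(15, "RP")
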