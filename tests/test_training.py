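import numpy as np
import pytest

from mnlnet.io import SegmentTable
from mnlnet.network import ArchitectureSpec, build_model
from mnlnet.preprocessing import build_task_dataset, segment_records
from mnlnet.synthetic import SyntheticSpec, generate_bonn_like
from mnlnet.training import TrainConfig, cross_validate, make_folds, train_fold


def fake_table(n_per_class, n_classes, seg_len=30, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return SegmentTable(rng.standard_normal((n, seg_len)), labels,
                        np.array(["A", "B", "C", "D", "E"])[labels % 5],
                        np.zeros(n, int), np.arange(n))


class TestMakeFolds:
    def test_stratified_counts(self):
        folds = make_folds(fake_table(230, 2), k=10, seed=1)
        for f in folds.test_indices:
            assert len(f) == 46  # 23 per class per fold
        assert folds.class_counts[0] == [23] * 10

    def test_partition_property(self):
        table = fake_table(37, 3)
        folds = make_folds(table, k=5, seed=2)
        all_idx = np.concatenate(folds.test_indices)
        assert len(all_idx) == len(table)
        assert len(np.unique(all_idx)) == len(table)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.intersect1d(folds.test_indices[i],
                                          folds.test_indices[j]).size

    def test_near_equal_split_with_remainder(self):
        folds = make_folds(fake_table(23, 2), k=10, seed=0)
        counts = folds.class_counts[0]
        assert sorted(set(counts)) in ([2, 3], [2], [3])
        assert sum(counts) == 23

    def test_deterministic_given_seed(self):
        t = fake_table(40, 2)
        a = make_folds(t, k=4, seed=9)
        b = make_folds(t, k=4, seed=9)
        for fa, fb in zip(a.test_indices, b.test_indices):
            assert np.array_equal(fa, fb)
        c = make_folds(t, k=4, seed=10)
        assert any(not np.array_equal(fa, fc)
                   for fa, fc in zip(a.test_indices, c.test_indices))

    def test_class_smaller_than_k(self):
        with pytest.raises(ValueError, match="fewer than k"):
            make_folds(fake_table(5, 2), k=10, seed=0)


@pytest.fixture(scope="module")
def separable_task():
    recs = generate_bonn_like(SyntheticSpec(n_records_per_set=4, seed=21,
                                            separability=5.0))
    return build_task_dataset(segment_records(recs), "A-E")


class TestTrainFold:
    def test_learns_separable_task(self, separable_task):
        task = separable_task
        model = build_model(ArchitectureSpec(n_classes=2), seed=4)
        config = TrainConfig(max_epochs=10, batch_size=50, seed=4)
        state, history = train_fold(model, task.segments, task.labels, config)
        assert history["best_val_accuracy"] >= 0.95
        assert state is not None

    def test_checkpoint_is_best_epoch(self, separable_task):
        task = separable_task
        model = build_model(ArchitectureSpec(n_classes=2), seed=5)
        config = TrainConfig(max_epochs=4, batch_size=50, seed=5)
        _, history = train_fold(model, task.segments, task.labels, config)
        accs = history["val_accuracy"]
        assert history["best_val_accuracy"] == max(accs)
        assert accs[history["best_epoch"]] == max(accs)

    def test_lr_schedule_decays_by_factor_on_plateau(self):
        # pure-noise task: validation accuracy plateaus quickly
        table = fake_table(60, 2, seg_len=178, seed=3)
        model = build_model(ArchitectureSpec(n_classes=2), seed=3)
        config = TrainConfig(max_epochs=8, batch_size=60,
                             plateau_patience_epochs=2, seed=3)
        _, history = train_fold(model, table.segments, table.labels, config)
        lrs = np.array(history["lr"])
        assert np.all(np.diff(lrs) <= 1e-15)  # non-increasing
        changes = lrs[1:][np.diff(lrs) < 0] / lrs[:-1][np.diff(lrs) < 0]
        assert len(changes) >= 1
        assert np.allclose(changes, 0.1)

    def test_identical_seed_identical_history(self):
        table = fake_table(40, 2, seg_len=178, seed=6)
        h = []
        for _ in range(2):
            model = build_model(ArchitectureSpec(n_classes=2), seed=7)
            config = TrainConfig(max_epochs=3, batch_size=40, seed=7)
            _, history = train_fold(model, table.segments, table.labels, config)
            h.append(history)
        assert h[0] == h[1]

    def test_empty_training_data(self):
        model = build_model(ArchitectureSpec(n_classes=2), seed=0)
        with pytest.raises(ValueError):
            train_fold(model, np.zeros((0, 178)), np.zeros(0, int), TrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=0.6)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


class TestCrossValidate:
    def test_report_layout_and_mean_identity(self, small_segments):
        config = TrainConfig(max_epochs=2, batch_size=64, seed=13)
        report = cross_validate(small_segments, "A-E", config, k=3)
        for metric, vals in report.fold_metrics.items():
            assert len(vals) == 3
            assert report.mean(metric) == pytest.approx(np.mean(vals), abs=1e-9)
        assert set(report.fold_metrics) == {"accuracy", "precision",
                                            "sensitivity", "specificity", "f1"}

    def test_reproducible_bit_for_bit(self, small_segments):
        config = TrainConfig(max_epochs=2, batch_size=64, seed=17)
        r1 = cross_validate(small_segments, "A-E", config, k=3)
        r2 = cross_validate(small_segments, "A-E", config, k=3)
        assert r1.to_dict() == r2.to_dict()

    def test_multiclass_scheme(self, small_segments):
        config = TrainConfig(max_epochs=1, batch_size=64, seed=19)
        report = cross_validate(small_segments, "AB-CD-E", config, k=3)
        assert len(report.fold_metrics["accuracy"]) == 3
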