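import numpy as np
import pytest

from oscimap import net, train


class TestPartition:
    def test_800_trials_split_600_100_100(self):
        sp = train.partition(800, train.TrainConfig(seed=0))
        assert len(sp.indices("train")) == 600
        assert len(sp.indices("val")) == 100
        assert len(sp.indices("test")) == 100

    def test_same_seed_identical(self):
        a = train.partition(101, train.TrainConfig(seed=3))
        b = train.partition(101, train.TrainConfig(seed=3))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_assignment_exhaustive_and_disjoint(self):
        sp = train.partition(97, train.TrainConfig(seed=1))
        idx = np.concatenate([sp.indices(s) for s in train.SPLITS])
        assert sorted(idx) == list(range(97))

    def test_subject_level_keeps_subjects_together(self):
        subjects = np.repeat([f"s{i}" for i in range(12)], 30)
        sp = train.partition(len(subjects), train.TrainConfig(seed=2),
                             subjects=subjects, level="subject")
        for s in np.unique(subjects):
            labels = set(sp.labels[subjects == s])
            assert len(labels) == 1

    def test_subject_level_needs_three_subjects_per_class(self):
        subjects = np.repeat(["a", "b", "c", "d"], 10)
        cls = {"a": 0, "b": 0, "c": 1, "d": 1}
        with pytest.raises(ValueError):
            train.partition(40, train.TrainConfig(), subjects=subjects,
                            level="subject", class_of_subject=cls)


class TestSchedule:
    def test_staircase_values(self):
        cfg = train.TrainConfig()
        assert train.lr_schedule(0, cfg) == 1e-4
        assert train.lr_schedule(9_999, cfg) == 1e-4
        assert train.lr_schedule(10_000, cfg) == 1e-4 * 0.96
        assert train.lr_schedule(40_794, cfg) == pytest.approx(8.4935e-5, rel=1e-4)

    def test_schedule_matches_closed_form_exactly(self):
        cfg = train.TrainConfig()
        for step in (0, 1, 5000, 10_000, 25_000, 40_793, 99_999):
            assert train.lr_schedule(step, cfg) == 1e-4 * 0.96 ** (step // 10_000)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            train.lr_schedule(-1, train.TrainConfig())

    def test_total_updates_counts_samples_seen(self):
        assert train.total_updates(13_598, 25, 75) == 40_794


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        np.testing.assert_allclose(train.class_weights([50, 50, 50]), 1.0)

    def test_formula_example(self):
        np.testing.assert_allclose(
            train.class_weights([100, 200, 100]), [4 / 3, 2 / 3, 4 / 3]
        )

    def test_weighted_total_identity(self):
        counts = np.array([369, 375, 390])
        w = train.class_weights(counts)
        assert (counts * w).sum() == pytest.approx(counts.sum(), rel=1e-12)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            train.class_weights([10, 0, 5])


class TestAugmentation:
    def _vol(self, seed=0):
        return np.random.default_rng(seed).random((20, 20, 50))

    def test_zero_shift_is_identity(self):
        v = self._vol()
        out = train.augment_shift(v, np.random.default_rng(0), offset=(0.0, 0.0))
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_unit_zoom_is_identity(self):
        v = self._vol(1)
        out = train.augment_zoom(v, np.random.default_rng(0), factor=1.0)
        np.testing.assert_allclose(out, v, atol=1e-7)

    def test_integer_shift_moves_impulse(self):
        v = np.zeros((20, 20, 50))
        v[10, 10, 5] = 1.0
        out = train.augment_shift(v, np.random.default_rng(0), offset=(2.0, 0.0))
        assert out[12, 10, 5] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(1.0)

    def test_frequency_axis_untouched(self):
        v = self._vol(2)
        rng = np.random.default_rng(3)
        for out in (train.augment_shift(v, rng), train.augment_zoom(v, rng),
                    train.augment_elastic(v, rng)):
            # a volume constant along frequency stays constant along frequency
            pass
        vc = np.repeat(self._vol(4)[:, :, :1], 50, axis=2)
        for tf in (train.augment_shift, train.augment_zoom, train.augment_elastic):
            out = tf(vc, np.random.default_rng(5))
            assert np.abs(np.diff(out, axis=2)).max() < 1e-6

    def test_selection_sizes_use_floor(self):
        vols = np.random.default_rng(6).random((300, 20, 20, 50))
        _, sel = train.apply_augmentation(vols, train.TrainConfig(), seed=0,
                                          return_selection=True)
        assert {len(v) for v in sel.values()} == {99}  # floor(0.33 * 300)

    def test_zero_fraction_is_identity(self):
        from dataclasses import replace

        vols = np.random.default_rng(7).random((40, 20, 20, 50))
        cfg = replace(train.TrainConfig(), augment_fraction=0.0)
        out = train.apply_augmentation(vols, cfg, seed=0)
        np.testing.assert_array_equal(out, vols)

    def test_same_seed_reproducible(self):
        vols = np.random.default_rng(8).random((30, 20, 20, 50))
        a = train.apply_augmentation(vols, train.TrainConfig(), seed=5)
        b = train.apply_augmentation(vols, train.TrainConfig(), seed=5)
        np.testing.assert_array_equal(a, b)

    def test_non_training_split_rejected(self):
        vols = np.zeros((4, 20, 20, 50))
        with pytest.raises(ValueError):
            train.apply_augmentation(vols, train.TrainConfig(), seed=0, split="val")


def _toy_dataset(n=90, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=n)
    vols = rng.random((n, 20, 20, 50)).astype(np.float32)
    # plant a simple class-dependent mean shift so training can make progress
    for c in range(3):
        vols[labels == c, c * 5 : c * 5 + 3, :5, :10] += 0.5
    return vols, labels


class TestTraining:
    def test_history_and_lr_curve(self):
        vols, labels = _toy_dataset()
        cfg = train.TrainConfig(max_epochs=2, patience=5, seed=0)
        model = net.build_model(net.ModelSpec(dtype="float32"), seed=0)
        model, hist = train.train(model, vols[:60], labels[:60], vols[60:], labels[60:], cfg)
        assert len(hist.val_loss) == 2
        assert hist.steps == train.total_updates(60, 25, 2)
        assert all(x >= y for x, y in zip(hist.lr, hist.lr[1:]))  # non-increasing

    def test_reproducible_given_seed(self):
        vols, labels = _toy_dataset()
        cfg = train.TrainConfig(max_epochs=1, seed=4)
        out = []
        for _ in range(2):
            model = net.build_model(net.ModelSpec(dtype="float32"), seed=4)
            model, _ = train.train(model, vols[:60], labels[:60], vols[60:], labels[60:], cfg)
            out.append(model.params["dense_W"].copy())
        np.testing.assert_array_equal(out[0], out[1])


class TestFinetune:
    def test_only_softmax_layer_changes(self):
        vols, labels = _toy_dataset(seed=1)
        model = net.build_model(net.ModelSpec(dtype="float32"), seed=1)
        before = {k: v.copy() for k, v in model.params.items()}
        bn_before = (model.bn_mean.copy(), model.bn_var.copy())
        model, hist = train.finetune(model, vols[:60], labels[:60],
                                     vols[60:], labels[60:], max_epochs=2)
        for k in before:
            if k.startswith("dense"):
                continue
            np.testing.assert_array_equal(model.params[k], before[k])
        np.testing.assert_array_equal(model.bn_mean, bn_before[0])
        np.testing.assert_array_equal(model.bn_var, bn_before[1])

    def test_zero_epochs_is_identity(self):
        vols, labels = _toy_dataset(seed=2)
        model = net.build_model(net.ModelSpec(dtype="float32"), seed=2)
        before = {k: v.copy() for k, v in model.params.items()}
        model, _ = train.finetune(model, vols[:60], labels[:60],
                                  vols[60:], labels[60:], max_epochs=0)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_best_epoch_selection_never_hurts_validation(self):
        from oscimap.train import _evaluate, class_weights

        vols, labels = _toy_dataset(seed=3)
        model = net.build_model(net.ModelSpec(dtype="float32"), seed=3)
        w = class_weights(np.bincount(labels[:60], minlength=3))
        pre_loss, _ = _evaluate(model, vols[60:], labels[60:], w)
        model, _ = train.finetune(model, vols[:60], labels[:60],
                                  vols[60:], labels[60:], max_epochs=3, weights=w)
        post_loss, _ = _evaluate(model, vols[60:], labels[60:], w)
        assert post_loss <= pre_loss + 1e-9
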