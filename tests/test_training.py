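"""Loss properties, fold hygiene and training-loop contracts."""

import numpy as np
import pytest
from dataclasses import replace

from ecgdelnet import (ArchitectureConfig, SimulationSpec, generate_dataset,
                       jaccard_loss, make_folds, train)
from ecgdelnet.training import (FoldSplit, LabelledRecord, TrainConfig,
                                _windows_for_subject, jaccard_loss_grad)


class TestJaccardLoss:
    def test_zero_iff_prediction_equals_binary_target(self):
        t = (np.random.default_rng(0).random((2, 3, 40)) > 0.5).astype(float)
        assert jaccard_loss(t, t) == pytest.approx(0.0)

    def test_disjoint_prediction_approaches_one(self):
        t = np.zeros((1, 3, 100))
        t[:, :, :50] = 1.0
        loss = jaccard_loss(1.0 - t, t)
        assert 0.95 < loss <= 1.0

    def test_matches_hand_computed_case(self):
        # one channel, 8 samples: inter = 0.5*1+0.25*1 = 0.75; sums p=1.95, t=3
        pred = np.array([[[0.5, 0.25, 0.1, 0.0, 0.9, 0.2, 0.0, 0.0]]])
        target = np.array([[[1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0]]])
        inter = 0.5 + 0.25 + 0.2
        union = pred.sum() + 3.0 - inter
        expected = 1.0 - (inter + 1.0) / (union + 1.0)
        assert jaccard_loss(pred, target) == pytest.approx(expected)

    def test_bounded_and_shape_checked(self):
        rng = np.random.default_rng(1)
        p = rng.random((2, 3, 30))
        t = (rng.random((2, 3, 30)) > 0.7).astype(float)
        assert 0.0 <= jaccard_loss(p, t) <= 1.0
        with pytest.raises(ValueError):
            jaccard_loss(p, t[:, :, :10])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        p = rng.random((1, 3, 20))
        t = (rng.random((1, 3, 20)) > 0.5).astype(float)
        loss, grad = jaccard_loss_grad(p, t)
        eps = 1e-7
        for idx in [(0, 0, 3), (0, 1, 10), (0, 2, 19)]:
            p[idx] += eps
            lp = jaccard_loss(p, t)
            p[idx] -= 2 * eps
            lm = jaccard_loss(p, t)
            p[idx] += eps
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestMakeFolds:
    def test_partition_is_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(10)]
        folds = make_folds(ids, k=5, seed=0)
        all_test = [s for f in range(5) for s in folds.test_subjects(f)]
        assert sorted(all_test) == sorted(ids)
        for f in range(5):
            assert len(folds.test_subjects(f)) == 2
            assert not set(folds.train_subjects(f)) & set(folds.test_subjects(f))

    def test_deterministic_per_seed(self):
        ids = [f"s{i}" for i in range(12)]
        assert make_folds(ids, 5, seed=3) == make_folds(ids, 5, seed=3)
        assert make_folds(ids, 5, seed=3) != make_folds(ids, 5, seed=4)

    def test_no_subject_leakage_over_many_seeds(self):
        ids = [f"s{i}" for i in range(9)]
        for seed in range(1000):
            folds = make_folds(ids, 3, seed=seed)
            for f in range(3):
                assert not set(folds.train_subjects(f)) & set(folds.test_subjects(f))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5, seed=0)


class TestTrainConfig:
    def test_pretraining_stage_disallows_augmentation(self):
        from ecgdelnet import AugmentationPolicy
        with pytest.raises(ValueError, match="pre-training"):
            TrainConfig(label_quality="low", augmentation=AugmentationPolicy())


@pytest.fixture(scope="module")
def tiny_dataset():
    spec = SimulationSpec(n_subjects=5, duration=8.0, seed=21)
    return [LabelledRecord(record=r, fiducials=f) for r, f in generate_dataset(spec)]


@pytest.fixture(scope="module")
def tiny_setup():
    arch = ArchitectureConfig(levels=4, blocks_per_level=2, base_width=2, seed=0)
    cfg = TrainConfig(window=256, epochs=2, batch_size=8, seed=5)
    return arch, cfg


class TestTrainLoop:
    def test_window_extraction_shapes(self, tiny_dataset):
        cfg = TrainConfig(window=256)
        samples = _windows_for_subject(tiny_dataset[0], cfg)
        assert samples, "expected at least one window"
        for x, t, onsets in samples:
            assert x.shape == (1, 256) and t.shape == (3, 256)
            assert all(0 <= o < 256 for o in onsets)

    def test_multi_lead_windows_stack_leads(self, tiny_dataset):
        cfg = TrainConfig(window=256, strategy="multi_lead")
        x, t, _ = _windows_for_subject(tiny_dataset[0], cfg)[0]
        assert x.shape == (2, 256)

    def test_seeded_run_reproduces_loss_history(self, tiny_dataset, tiny_setup):
        arch, cfg = tiny_setup
        folds = make_folds([d.record.record_id for d in tiny_dataset], k=5, seed=1)
        one_fold = FoldSplit(k=1, folds=(folds.folds[0],), seed=1)
        h1 = train(tiny_dataset, one_fold, arch, cfg)[0].history
        h2 = train(tiny_dataset, one_fold, arch, cfg)[0].history
        assert h1 == h2

    def test_fold_isolation_test_subjects_never_touch_training(self, tiny_dataset,
                                                               tiny_setup):
        """Replacing every test subject's data with garbage leaves the training
        loss history bit-identical: leakage is impossible by construction."""
        arch, cfg = tiny_setup
        folds = make_folds([d.record.record_id for d in tiny_dataset], k=5, seed=1)
        one_fold = FoldSplit(k=1, folds=(folds.folds[0],), seed=1)
        h_ref = train(tiny_dataset, one_fold, arch, cfg)[0].history
        test_ids = set(one_fold.test_subjects(0))
        mangled = []
        for item in tiny_dataset:
            if item.record.record_id in test_ids:
                rec = item.record
                garbage = replace_signal(rec, np.random.default_rng(0).normal(
                    size=rec.signal.shape))
                mangled.append(LabelledRecord(record=garbage, fiducials=item.fiducials))
            else:
                mangled.append(item)
        h_mangled = train(mangled, one_fold, arch, cfg)[0].history
        assert h_ref == h_mangled

    def test_empty_training_fold_raises(self, tiny_dataset, tiny_setup):
        arch, cfg = tiny_setup
        empty = FoldSplit(k=1, folds=(((), ("sub000",)),), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(tiny_dataset, empty, arch, cfg)


def replace_signal(record, signal):
    from ecgdelnet import ECGRecord
    return ECGRecord(record_id=record.record_id, fs=record.fs, signal=signal,
                     lead_names=list(record.lead_names))


def test_pretrain_then_finetune_protocol(tiny_dataset):
    from ecgdelnet import degrade_labels, pretrain_then_finetune
    data = [LabelledRecord(record=d.record, fiducials=d.fiducials,
                           low_quality=degrade_labels(d.fiducials, 250.0, seed=3))
            for d in tiny_dataset]
    folds = FoldSplit(k=1, folds=((("sub000", "sub001", "sub002"),
                                   ("sub003", "sub004")),), seed=0)
    arch = ArchitectureConfig(levels=4, blocks_per_level=2, base_width=2, seed=0)
    pre_cfg = TrainConfig(window=256, epochs=1, batch_size=8, label_quality="low")
    fine_cfg = TrainConfig(window=256, epochs=1, batch_size=8)
    pre_runs, fine_runs = pretrain_then_finetune(data, folds, arch, pre_cfg, fine_cfg)
    assert pre_runs[0].test_subjects == fine_runs[0].test_subjects
    # stage-1-only model still emits a valid 3-channel probability mask
    y = pre_runs[0].model.forward(np.zeros((1, 1, 256)))
    assert y.shape == (1, 3, 256) and 0.0 <= y.min() and y.max() <= 1.0
    # stage order enforcement
    with pytest.raises(ValueError):
        pretrain_then_finetune(data, folds, arch, fine_cfg, fine_cfg)


def test_experiment_grid_produces_row_per_config_fold_wave(tiny_dataset):
    from ecgdelnet import run_experiment_grid
    arch = ArchitectureConfig(levels=4, blocks_per_level=2, base_width=2, seed=0)
    cfg = TrainConfig(window=256, epochs=1, batch_size=8, seed=5)
    folds = FoldSplit(k=1, folds=((("sub000", "sub001", "sub002", "sub003"),
                                   ("sub004",)),), seed=0)
    grid = [{"spatial_dropout_p": 0.0}, {"spatial_dropout_p": 0.25}]
    table = run_experiment_grid(grid, tiny_dataset, folds, arch, cfg, window=256)
    assert len(table) == 2 * 1 * 3  # configs x folds x waves
    assert {"precision", "recall", "f1", "onset_sd_ms"} <= set(table.columns)
    assert set(table["spatial_dropout_p"]) == {"0.0", "0.25"}
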