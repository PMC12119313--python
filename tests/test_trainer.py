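"""Training protocol: schedule arithmetic, preprocessing, the loop, folds."""

import dataclasses

import numpy as np
import pytest

from dualdistill import (
    ObjectiveConfig,
    SynthParams,
    TrainConfig,
    crossvalidate,
    default_model_factory,
    evaluate,
    generate_dataset,
    lr_at,
    preprocess,
    smoke_config,
    stratified_fold_indices,
    stratified_split,
    train,
)


class TestLrSchedule:
    def test_reference_values(self):
        cfg = TrainConfig(epochs=100, warmup_epochs=10, milestones=(50, 75))
        assert lr_at(10, cfg) == pytest.approx(0.001)  # plateau after warmup
        assert lr_at(4, cfg) == pytest.approx(0.0005)  # 5th epoch of warmup
        assert lr_at(60, cfg) == pytest.approx(0.0001)  # one milestone passed
        assert lr_at(80, cfg) == pytest.approx(0.00001)  # both passed

    def test_piecewise_monotone(self):
        cfg = TrainConfig(epochs=40, warmup_epochs=5)
        lrs = [lr_at(e, cfg) for e in range(40)]
        warm = lrs[: cfg.warmup_epochs]
        rest = lrs[cfg.warmup_epochs :]
        assert all(b >= a for a, b in zip(warm, warm[1:]))
        assert all(b <= a for a, b in zip(rest, rest[1:]))

    def test_out_of_range(self):
        cfg = TrainConfig(epochs=10, warmup_epochs=2)
        with pytest.raises(ValueError):
            lr_at(10, cfg)

    def test_default_milestones_at_half_and_three_quarters(self):
        assert TrainConfig(epochs=100).resolved_milestones() == (50, 75)


class TestConfigValidation:
    def test_zero_clip_norm_rejected(self):
        with pytest.raises(ValueError, match="clip_norm"):
            TrainConfig(clip_norm=0.0)

    def test_warmup_longer_than_epochs_rejected(self):
        with pytest.raises(ValueError, match="warmup"):
            TrainConfig(epochs=5, warmup_epochs=10)

    def test_decay_factor_bounds(self):
        with pytest.raises(ValueError, match="decay"):
            TrainConfig(decay_factor=1.0)


class TestPreprocess:
    def test_eval_mode_deterministic(self, tiny_params, tiny_train_config):
        clip, _ = generate_dataset((1, 0, 0), tiny_params, seed=1)
        a = preprocess(clip[0], tiny_train_config, train_mode=False)
        b = preprocess(clip[0], tiny_train_config, train_mode=False)
        np.testing.assert_array_equal(a, b)

    def test_output_spatial_size(self, tiny_params):
        cfg = smoke_config(input_size=28, frames_per_clip=5)
        clip, _ = generate_dataset((1, 0, 0), tiny_params, seed=1)
        out = preprocess(clip[0], cfg, train_mode=True, seed=3)
        assert out.shape == (1, 5, 28, 28)

    def test_train_mode_seed_deterministic(self, tiny_params, tiny_train_config):
        clip, _ = generate_dataset((1, 0, 0), tiny_params, seed=1)
        a = preprocess(clip[0], tiny_train_config, train_mode=True, seed=9)
        b = preprocess(clip[0], tiny_train_config, train_mode=True, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_flip_fraction_matches_binomial(self):
        """Over 1000 seeded calls the flipped fraction is near 1/2."""
        cfg = smoke_config(input_size=8, frames_per_clip=2)
        base = np.zeros((1, 2, 16, 16))
        base[..., :8] = 1.0  # left half bright: flips are detectable
        flipped = 0
        for seed in range(1000):
            out = preprocess(base, cfg, train_mode=True, seed=seed)
            flipped += out[0, 0, :, :4].mean() < out[0, 0, :, 4:].mean()
        assert 0.45 <= flipped / 1000 <= 0.55

    def test_short_clip_loops(self, tiny_params):
        cfg = smoke_config(input_size=16, frames_per_clip=12)
        clip, _ = generate_dataset((1, 0, 0), tiny_params, seed=1)  # 8 frames
        out = preprocess(clip[0], cfg, train_mode=False)
        assert out.shape[1] == 12

    def test_empty_clip_rejected(self, tiny_train_config):
        with pytest.raises(ValueError, match="nonempty"):
            preprocess(np.zeros((1, 0, 16, 16)), tiny_train_config, train_mode=False)

    def test_grayscale_collapses_rgb_statistics(self, tiny_params, tiny_train_config):
        clip, _ = generate_dataset((1, 0, 0), tiny_params, seed=1)
        mono = preprocess(clip[0], tiny_train_config, train_mode=False)
        rgb = preprocess(clip[0].to_rgb(), tiny_train_config, train_mode=False)
        assert mono.shape[0] == 1 and rgb.shape[0] == 3


class TestTrainLoop:
    def test_loss_decreases_history_complete(self, tiny_params):
        """Five-seed smoke oracle: 5 epochs on 30 clips lowers the mean loss."""
        firsts, lasts = [], []
        for seed in range(5):
            clips, _ = generate_dataset((10, 10, 10), tiny_params, seed=40 + seed)
            cfg = smoke_config(
                epochs=5, warmup_epochs=1, input_size=24, frames_per_clip=6, batch_size=6, seed=seed
            )
            model = default_model_factory(widths=(2, 4, 6, 8))(seed)
            _, history = train(clips, model, cfg)
            assert len(history) == 5
            assert history.lrs == [lr_at(e, cfg) for e in range(5)]
            for epoch in history.losses:
                assert all(np.isfinite(v) for v in epoch.values())
            firsts.append(history.losses[0]["total"])
            lasts.append(history.losses[-1]["total"])
        assert np.mean(lasts) < np.mean(firsts)
        assert sum(l < f for f, l in zip(firsts, lasts)) >= 3

    def test_reproducible_history(self, tiny_params):
        clips, _ = generate_dataset((2, 2, 2), tiny_params, seed=4)
        cfg = smoke_config(epochs=2, input_size=16, frames_per_clip=4, batch_size=6, seed=5)
        runs = []
        for _ in range(2):
            model = default_model_factory(widths=(2, 4, 6, 8))(1)
            _, h = train(clips, model, cfg)
            runs.append(h.losses)
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self, toy_model, tiny_train_config):
        with pytest.raises(ValueError, match="empty"):
            train([], toy_model, tiny_train_config)

    def test_evaluate_reports_scores_and_auc(self, tiny_params, tiny_train_config):
        clips, _ = generate_dataset((2, 2, 2), tiny_params, seed=6)
        model = default_model_factory(widths=(2, 4, 6, 8))(3)
        report, scores, preds = evaluate(model, clips, tiny_train_config)
        assert scores.shape == (6, 3)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-5)
        assert preds.shape == (6,)
        assert report.auc_per_class.shape == (3,)


class TestSplitting:
    def test_reference_fold_sizes(self):
        """317 items in the 124/80/113 class split partition into test folds
        of sizes {64, 64, 63, 63, 63}."""
        labels = np.array([0] * 124 + [1] * 80 + [2] * 113)
        folds = stratified_fold_indices(labels, 5, seed=0)
        assert sorted(len(f) for f in folds) == [63, 63, 63, 64, 64]
        np.testing.assert_array_equal(np.sort(np.concatenate(folds)), np.arange(317))

    def test_stratification_on_balanced_set(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        folds = stratified_fold_indices(labels, 2, seed=1)
        for fold in folds:
            counts = np.bincount(labels[fold], minlength=3)
            np.testing.assert_array_equal(counts, [2, 2, 2])

    def test_fold_determinism(self):
        labels = np.repeat([0, 1, 2], 10)
        a = stratified_fold_indices(labels, 5, seed=9)
        b = stratified_fold_indices(labels, 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_small_class_suggests_smaller_k(self):
        with pytest.raises(ValueError, match="smaller k"):
            stratified_fold_indices([0, 0, 0, 1], 3)

    def test_split_ratio(self):
        labels = np.repeat([0, 1, 2], 10)
        tr, te = stratified_split(labels, 0.8, seed=0)
        assert len(tr) == 24 and len(te) == 6
        assert len(np.intersect1d(tr, te)) == 0


def test_crossvalidate_end_to_end(tiny_params):
    """Tiny 2-fold CV run: per-fold reports plus mean ± std aggregation."""
    clips, _ = generate_dataset((4, 4, 4), tiny_params, seed=19)
    cfg = smoke_config(epochs=2, input_size=16, frames_per_clip=4, batch_size=6, seed=3)
    cfg = dataclasses.replace(cfg, folds=2)
    factory = default_model_factory(widths=(2, 4, 6, 8))
    reports, summary = crossvalidate(clips, cfg, ObjectiveConfig(), factory)
    assert len(reports) == 2
    assert "±" in summary["accuracy"]["formatted"]
    assert 0.0 <= summary["accuracy"]["mean"] <= 1.0
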