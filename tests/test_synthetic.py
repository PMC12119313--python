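"""The synthetic plaque-video generator: determinism, class structure,
probe-jump phenomenology, dataset plumbing."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from dualdistill import (
    SynthParams,
    VideoClip,
    generate_clip,
    generate_dataset,
    inject_probe_jump,
    load_dataset,
    write_dataset,
)


def frame_corr(a, b):
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def adjacent_corrs(pixels):
    frames = pixels[0]
    return np.array([frame_corr(frames[t], frames[t + 1]) for t in range(len(frames) - 1)])


class TestGenerateClip:
    def test_deterministic_bit_identical(self, tiny_params):
        a = generate_clip(1, tiny_params, seed=5)
        b = generate_clip(1, tiny_params, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_invalid_label_names_range(self, tiny_params):
        with pytest.raises(ValueError, match="0, 1, 2"):
            generate_clip(3, tiny_params, seed=0)

    def test_noiseless_bright_class_peaks_inside_blob(self):
        params = SynthParams(n_frames=6, height=32, width=32, speckle_sigma=0.0, jump_rate=0.0)
        clip = generate_clip(0, params, seed=2)
        mask = clip.meta["mask"]
        for t in range(clip.n_frames):
            peak = np.unravel_index(np.argmax(clip.pixels[0, t]), clip.pixels[0, t].shape)
            assert mask[t][peak]

    def test_bright_class_interior_brighter_than_dark_class(self, tiny_params):
        """Oracle: mean interior intensity straight from the generated masks."""
        bright = generate_clip(0, tiny_params, seed=9)
        dark = generate_clip(1, tiny_params, seed=9)
        m_bright = np.mean([bright.pixels[0, t][bright.meta["mask"][t]].mean() for t in range(bright.n_frames)])
        m_dark = np.mean([dark.pixels[0, t][dark.meta["mask"][t]].mean() for t in range(dark.n_frames)])
        assert m_bright > m_dark

    def test_drift_bounded_between_jumps(self):
        params = SynthParams(n_frames=12, height=32, width=32, drift_step=1.5, jump_rate=0.0)
        clip = generate_clip(2, params, seed=3)
        centers = clip.meta["centers"]
        steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        assert np.all(steps <= params.drift_step + 1e-9)

    def test_pixels_in_unit_interval(self, tiny_params):
        clip = generate_clip(2, tiny_params, seed=4)
        assert clip.pixels.min() >= 0.0 and clip.pixels.max() <= 1.0


class TestInjectProbeJump:
    def test_zero_displacement_same_noise_seed_is_identity(self, tiny_params):
        clip = generate_clip(0, SynthParams(n_frames=8, jump_rate=0.0), seed=6)
        out = inject_probe_jump(clip, jump_time=4, displacement=0.0, seed=clip.meta["noise_seed"])
        assert np.array_equal(out.pixels, clip.pixels)

    def test_jump_time_out_of_range(self, tiny_params):
        clip = generate_clip(0, tiny_params, seed=6)
        with pytest.raises(ValueError, match="jump_time"):
            inject_probe_jump(clip, jump_time=0, displacement=3.0, seed=1)
        with pytest.raises(ValueError, match="jump_time"):
            inject_probe_jump(clip, jump_time=tiny_params.n_frames, displacement=3.0, seed=1)

    def test_jump_breaks_adjacent_similarity(self):
        """Oracle: correlations computed directly from pixels."""
        params = SynthParams(n_frames=16, height=48, width=48, jump_rate=0.0, drift_step=0.5)
        clip = generate_clip(0, params, seed=13)
        jt = 8
        out = inject_probe_jump(clip, jump_time=jt, displacement=16.0, seed=99)
        corrs = adjacent_corrs(out.pixels)
        jump_corr = corrs[jt - 1]
        within = np.delete(corrs, jt - 1)
        assert jump_corr < within.mean()

    def test_distant_frames_more_similar_than_jump_neighbors(self):
        """A post-return frame resembles the first frame more than the two
        frames straddling the jump resemble each other."""
        params = SynthParams(n_frames=16, height=48, width=48, jump_rate=0.0, drift_step=0.5)
        clip = generate_clip(0, params, seed=13)
        jt = 8
        out = inject_probe_jump(clip, jump_time=jt, displacement=16.0, seed=99)
        frames = out.pixels[0]
        jump_corr = frame_corr(frames[jt - 1], frames[jt])
        post_return = max(frame_corr(frames[0], frames[t]) for t in range(jt + 1, out.n_frames))
        assert post_return > jump_corr


class TestGenerateDataset:
    def test_counts_and_labels(self, tiny_params):
        clips, manifest = generate_dataset((4, 4, 4), tiny_params, seed=1)
        assert len(clips) == 12 and len(manifest) == 12
        labels = [c.label for c in clips]
        assert labels.count(0) == labels.count(1) == labels.count(2) == 4

    def test_empty_request(self, tiny_params):
        clips, manifest = generate_dataset((0, 0, 0), tiny_params, seed=1)
        assert clips == [] and len(manifest) == 0
        assert list(manifest.columns) == ["clip_id", "path", "label", "n_frames"]

    def test_seed_changes_pixels_not_shape(self, tiny_params):
        a, ma = generate_dataset((1, 1, 1), tiny_params, seed=1)
        b, mb = generate_dataset((1, 1, 1), tiny_params, seed=2)
        assert ma.shape == mb.shape
        assert any(not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_determinism(self, tiny_params):
        a, _ = generate_dataset((2, 1, 1), tiny_params, seed=3)
        b, _ = generate_dataset((2, 1, 1), tiny_params, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)


def test_label_signal_knn_above_chance():
    """Classes must be learnable from first-order intensity statistics."""
    params = SynthParams()
    train, _ = generate_dataset((10, 10, 10), params, seed=21)
    test, _ = generate_dataset((5, 5, 5), params, seed=22)

    def feats(clips):
        return np.array([[c.pixels.mean(), c.pixels.var()] for c in clips])

    knn = KNeighborsClassifier(n_neighbors=3)
    knn.fit(feats(train), [c.label for c in train])
    acc = knn.score(feats(test), [c.label for c in test])
    assert acc > 1.0 / 3.0


def test_jump_rate_one_yields_low_correlation_break():
    """With jump_rate=1 every clip has an adjacent-frame correlation below
    the 10th percentile of its within-segment correlations."""
    params = SynthParams(n_frames=24, jump_rate=1.0, drift_step=0.5)
    clips, _ = generate_dataset((3, 3, 3), params, seed=33)
    for clip in clips:
        jt = clip.meta["jump_time"]
        assert jt is not None
        corrs = adjacent_corrs(clip.pixels)
        within = np.delete(corrs, jt - 1)
        assert corrs[jt - 1] < np.percentile(within, 10)


def test_write_and_load_roundtrip(tmp_path, tiny_params):
    clips, _ = generate_dataset((1, 1, 0), tiny_params, seed=2)
    manifest_path = write_dataset(clips, tmp_path / "ds")
    loaded = load_dataset(manifest_path)
    assert len(loaded) == 2
    for orig, back in zip(clips, loaded):
        assert back.label == orig.label
        # 8-bit quantisation bounds the roundtrip error
        assert np.max(np.abs(back.pixels - orig.pixels)) <= 1.0 / 255.0 + 1e-9


def test_videoclip_validation():
    with pytest.raises(ValueError, match="rank-4"):
        VideoClip(pixels=np.zeros((4, 4)), label=0, clip_id="x")
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        VideoClip(pixels=np.full((1, 4, 16, 16), 2.0), label=0, clip_id="x")


def test_to_rgb_replicates_channels(tiny_params):
    clip = generate_clip(0, tiny_params, seed=1)
    rgb = clip.to_rgb()
    assert rgb.pixels.shape[0] == 3
    assert np.array_equal(rgb.pixels[0], rgb.pixels[2])
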