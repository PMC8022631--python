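"""Loss arithmetic, augmentation semantics, sequence windows, dataset splits."""

import numpy as np
import pytest
from skimage import color as skcolor

from drhn.hierarchy import encode_label
from drhn.synthetic import (
    SceneParams,
    angle_to_label,
    generate_cohort,
    generate_stage2,
)
from drhn.training import (
    AugmentationParams,
    Recording,
    apply_augmentation,
    augment_sequence,
    bce_loss,
    make_sequences,
    split_dataset,
)


def bce_oracle(p, t, eps=1e-7):
    """Independent elementwise implementation of the summed cross-entropy."""
    total = 0.0
    for pi, ti in zip(p, t):
        pi = min(max(float(pi), eps), 1 - eps)
        total -= ti * np.log(pi) + (1 - ti) * np.log(1 - pi)
    return total


class TestBceLoss:
    def test_perfect_match_is_nearly_zero(self, tree):
        truth = encode_label(tree, "hunched over")
        assert bce_loss(truth, truth) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_prediction_is_eight_ln_two(self, tree):
        truth = encode_label(tree, "lying down")
        assert bce_loss(np.full(8, 0.5), truth) == pytest.approx(
            8 * np.log(2), rel=1e-12
        )

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(8)
            t = (rng.random(8) < 0.3).astype(float)
            assert bce_loss(p, t) == pytest.approx(bce_oracle(p, t), abs=1e-10)

    def test_saturated_predictions_are_clipped_not_infinite(self):
        t = np.array([1.0, 0.0])
        loss = bce_loss(np.array([0.0, 1.0]), t)
        assert np.isfinite(loss) and loss > 0

    def test_decreases_toward_truth(self, rng):
        t = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        p = rng.random(8)
        losses = [bce_loss(p + alpha * (t - p), t) for alpha in (0.0, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_non_binary_truth_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bce_loss(np.full(8, 0.5), np.full(8, 0.5))


class TestAugmentation:
    def frames(self, rng, t=3):
        return rng.random((t, 12, 16, 4)).astype(np.float32)

    def test_double_flip_restores_exactly(self, rng):
        x = self.frames(rng)
        twice = apply_augmentation(apply_augmentation(x, flip=True), flip=True)
        assert np.array_equal(twice, x)

    def test_hue_full_turn_is_identity(self, rng):
        x = self.frames(rng)
        out = apply_augmentation(x, hue_shift=2 * np.pi)
        assert np.allclose(out[..., :3], x[..., :3], atol=1e-6)

    def test_zero_saturation_gives_grayscale(self, rng):
        out = apply_augmentation(self.frames(rng), saturation=0.0)
        # HSV round-trip oracle: S=0 must mean R=G=B per pixel
        assert np.allclose(out[..., 0], out[..., 1], atol=1e-6)
        assert np.allclose(out[..., 1], out[..., 2], atol=1e-6)
        hsv = skcolor.rgb2hsv(out[0, ..., :3])
        assert np.allclose(hsv[..., 1], 0.0, atol=1e-6)

    def test_depth_channel_untouched_by_photometry(self, rng):
        x = self.frames(rng)
        out = apply_augmentation(x, hue_shift=1.0, saturation=1.7)
        assert np.array_equal(out[..., 3], x[..., 3])

    def test_flip_mirrors_depth_geometrically(self, rng):
        x = self.frames(rng)
        out = apply_augmentation(x, flip=True)
        assert np.array_equal(out[..., 3], x[:, :, ::-1, 3])

    def test_same_draw_for_all_frames(self, rng):
        # constant-in-time input must stay constant-in-time after augmentation
        one = rng.random((1, 12, 16, 4)).astype(np.float32)
        x = np.repeat(one, 4, axis=0)
        out = augment_sequence(x, AugmentationParams(), rng)
        for t in range(1, 4):
            assert np.array_equal(out[t], out[0])

    def test_outputs_stay_in_unit_range(self, rng):
        x = self.frames(rng)
        for _ in range(20):
            out = augment_sequence(x, AugmentationParams(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


def make_recording(n=100, label="sitting straight", subject="s00"):
    rng = np.random.default_rng(0)
    return Recording(
        subject_id=subject,
        camera_view="3 o'clock",
        frames=rng.random((n, 8, 8, 4)).astype(np.float32),
        labels=[label] * n,
        timestamps=np.arange(n, dtype=float),
    )


class TestMakeSequences:
    def test_homogeneous_segment_keeps_its_label(self):
        rec = make_recording(30, label="hunched over")
        out = make_sequences(rec, n=4, spacing_s=1.0)
        assert len(out) == 30 - 3
        assert all(lbl == "hunched over" for _, lbl in out)
        assert all(w.shape == (4, 8, 8, 4) for w, _ in out)

    def test_single_frame_windows_cover_all_frames(self):
        rec = make_recording(17)
        out = make_sequences(rec, n=1)
        assert len(out) == 17

    def test_too_short_recording_yields_empty_list(self):
        rec = make_recording(2)
        assert make_sequences(rec, n=4) == []

    def test_label_is_last_frame_in_stage2_sweep(self, subject, quiet_scene):
        rec = generate_stage2(
            subject, quiet_scene, np.random.default_rng(0), fps=1.0
        )
        for window, lbl in make_sequences(rec, n=3):
            # recover the window's position from its angle trace
            assert lbl in rec.labels
        out = make_sequences(rec, n=3)
        for start, (window, lbl) in enumerate(out):
            assert lbl == angle_to_label(rec.angles[start + 2])

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError, match="\\[1, 4\\]"):
            make_sequences(make_recording(), n=5)


class TestSplitDataset:
    def test_single_recording_arithmetic(self):
        rec = make_recording(100)
        train, test = split_dataset([rec], 0.9)
        assert len(train[0]) == 90 and len(test[0]) == 10
        assert np.array_equal(train[0].frames, rec.frames[:90])
        assert np.array_equal(test[0].frames, rec.frames[90:])

    def test_partition_no_shared_frames(self):
        recs = [make_recording(57, subject=f"s{i}") for i in range(3)]
        train, test = split_dataset(recs, 0.9)
        for tr, te, orig in zip(train, test, recs):
            assert len(tr) + len(te) == len(orig)
            assert tr.timestamps[-1] < te.timestamps[0]

    def test_cohort_ratio_within_two_points(self):
        recs = generate_cohort(n_subjects=3, seed=3, fps=0.2)
        train, test = split_dataset(recs, 0.9)
        per_subject: dict[str, list[int]] = {}
        for tr, te in zip(train, test):
            agg = per_subject.setdefault(tr.subject_id, [0, 0])
            agg[0] += len(tr)
            agg[1] += len(te)
        for sid, (ntr, nte) in per_subject.items():
            assert ntr / (ntr + nte) == pytest.approx(0.9, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no recordings"):
            split_dataset([], 0.9)

    def test_kfold_covers_every_recording_once(self):
        from drhn.training import kfold_recordings

        recs = [make_recording(10, subject=f"s{i}") for i in range(7)]
        seen = []
        for train, test in kfold_recordings(recs, k=3, seed=1):
            assert len(train) + len(test) == 7
            assert not {id(r) for r in train} & {id(r) for r in test}
            seen += [r.subject_id for r in test]
        assert sorted(seen) == sorted(r.subject_id for r in recs)
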