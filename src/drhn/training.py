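"""Training: multi-label cross-entropy, augmentation, sequence sampling, splits.

The network is trained as a multi-label classifier over the flattened posture
tree: each of the 8 sigmoid units gets an independent binary cross-entropy
term and the loss is their sum.  A training example is a short sequence of
1-4 RGB-D frames about a second apart, labelled by its *last* frame, so the
model's prediction is biased toward the most recent posture.

Augmentation draws one set of values per sequence (flip / hue / saturation,
each applied with probability 0.5) and applies them identically to every
frame, preserving temporal coherence.  The depth channel only ever undergoes
geometric ops — photometric jitter on a metric channel would be meaningless.

Splitting is subject-aware and temporal: each recording is cut at the 90%
point, the leading part feeding the train set and the trailing part the test
set, so near-duplicate neighbouring frames can never leak across the split.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import color as skcolor

from .hierarchy import PostureTree, build_default_tree, encode_label, root_label
from .model import DRHN
from .nn import Adam

__all__ = [
    "TrainingConfig",
    "AugmentationParams",
    "Recording",
    "bce_loss",
    "apply_augmentation",
    "augment_sequence",
    "make_sequences",
    "split_dataset",
    "train",
]

_EPS = 1e-7  # clip for predictions before logs; sigmoid saturates in float32


@dataclass
class TrainingConfig:
    learning_rate: float = 5e-4
    batch_size: int = 8
    optimizer: str = "adam"
    epochs: int = 50
    seed: int = 0
    frame_spacing_s: float = 1.0
    split_ratio: float = 0.9
    grad_clip_norm: float | None = 5.0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer!r}")


@dataclass
class AugmentationParams:
    p_flip: float = 0.5
    p_hue: float = 0.5
    p_saturation: float = 0.5
    hue_range: tuple[float, float] = (0.0, 2.0 * np.pi)
    saturation_range: tuple[float, float] = (0.0, 2.0)


@dataclass
class Recording:
    """One captured (or synthesized) RGB-D recording with per-frame labels.

    ``frames`` is [T, H, W, 4] float32 in [0, 1] (RGB + normalized depth);
    ``angles`` stores the latent spine angle when the recording is synthetic.
    """

    subject_id: str
    camera_view: str
    frames: np.ndarray
    labels: list[str]
    timestamps: np.ndarray
    angles: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.labels) != len(self.frames):
            raise ValueError("one label per frame required")
        ts = np.asarray(self.timestamps, dtype=np.float64)
        if len(ts) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps = ts

    def __len__(self) -> int:
        return len(self.frames)


def bce_loss(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Summed binary cross-entropy over the flattened tree units.

    ``-sum_i [y*_i log y_i + (1 - y*_i) log(1 - y_i)]`` with predictions
    clipped to [eps, 1-eps].  For a batch (2-D input) the per-sample sums are
    averaged.  Zero only in the limit of perfect prediction.
    """
    p = np.clip(np.asarray(predicted, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if np.any((t != 0.0) & (t != 1.0)):
        raise ValueError("ground-truth vector must be binary")
    per_unit = t * np.log(p) + (1.0 - t) * np.log(1.0 - p)
    total = -per_unit.sum(axis=-1)
    return float(total.mean())


def apply_augmentation(
    frames: np.ndarray,
    flip: bool = False,
    hue_shift: float | None = None,
    saturation: float | None = None,
) -> np.ndarray:
    """Deterministically apply one augmentation draw to a whole sequence.

    ``hue_shift`` is in radians; ``saturation`` a multiplicative factor.
    The depth channel (index 3) undergoes the geometric flip only.
    """
    out = np.asarray(frames, dtype=np.float32).copy()
    if flip:
        out = out[:, :, ::-1, :].copy()
    if hue_shift is not None or saturation is not None:
        rgb = out[..., :3].astype(np.float64)
        for i in range(rgb.shape[0]):
            hsv = skcolor.rgb2hsv(rgb[i])
            if hue_shift is not None:
                hsv[..., 0] = (hsv[..., 0] + hue_shift / (2.0 * np.pi)) % 1.0
            if saturation is not None:
                hsv[..., 1] = np.clip(hsv[..., 1] * saturation, 0.0, 1.0)
            rgb[i] = skcolor.hsv2rgb(hsv)
        out[..., :3] = np.clip(rgb, 0.0, 1.0).astype(np.float32)
    return out


def augment_sequence(
    frames: np.ndarray,
    params: AugmentationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly augment a sequence; identical draws for all frames in it."""
    flip = bool(rng.random() < params.p_flip)
    hue = (
        float(rng.uniform(*params.hue_range))
        if rng.random() < params.p_hue
        else None
    )
    sat = (
        float(rng.uniform(*params.saturation_range))
        if rng.random() < params.p_saturation
        else None
    )
    return apply_augmentation(frames, flip=flip, hue_shift=hue, saturation=sat)


def make_sequences(
    rec: Recording,
    n: int,
    spacing_s: float = 1.0,
    rng: np.random.Generator | None = None,
    max_sequences: int | None = None,
) -> list[tuple[np.ndarray, str]]:
    """Sliding windows of ``n`` frames ~``spacing_s`` apart from one recording.

    The window's label is that of its **last** frame.  A recording too short
    for a single window yields an empty list.  With ``max_sequences`` set, a
    random subset is drawn (seeded ``rng`` required), e.g. to cap epoch cost.
    """
    if not 1 <= n <= 4:
        raise ValueError("sequence length n must be in [1, 4]")
    if len(rec) == 0:
        return []
    dt = float(np.median(np.diff(rec.timestamps))) if len(rec) > 1 else spacing_s
    step = max(1, int(round(spacing_s / dt)))
    span = (n - 1) * step
    starts = list(range(0, len(rec) - span))
    if max_sequences is not None and len(starts) > max_sequences:
        if rng is None:
            raise ValueError("max_sequences requires a seeded rng")
        starts = sorted(rng.choice(len(starts), size=max_sequences, replace=False))
    out = []
    for s in starts:
        idx = range(s, s + span + 1, step)
        window = rec.frames[list(idx)]
        out.append((window, rec.labels[s + span]))
    return out


def split_dataset(
    recordings: Sequence[Recording], ratio: float = 0.9
) -> tuple[list[Recording], list[Recording]]:
    """Per-recording temporal split: leading ``ratio`` to train, tail to test.

    Every subject contributes to both sets; no frame appears in both.
    """
    if not recordings:
        raise ValueError("no recordings to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    train_set, test_set = [], []
    for rec in recordings:
        cut = int(len(rec) * ratio)
        cut = min(max(cut, 1), len(rec) - 1)  # both parts non-empty
        for part, lo, hi in ((train_set, 0, cut), (test_set, cut, len(rec))):
            part.append(
                Recording(
                    subject_id=rec.subject_id,
                    camera_view=rec.camera_view,
                    frames=rec.frames[lo:hi],
                    labels=rec.labels[lo:hi],
                    timestamps=rec.timestamps[lo:hi],
                    angles=None if rec.angles is None else rec.angles[lo:hi],
                    meta=dict(rec.meta),
                )
            )
    return train_set, test_set


def kfold_recordings(
    recordings: Sequence[Recording], k: int = 10, seed: int = 0
):
    """Yield (train, test) recording lists for k-fold over whole recordings.

    An alternative protocol to the temporal 90:10 split: entire recordings
    rotate into the test fold, so test subjects' other recordings may appear
    in training but no frames are shared.
    """
    if not 2 <= k <= len(recordings):
        raise ValueError(f"k must be in [2, {len(recordings)}]")
    order = np.random.default_rng(seed).permutation(len(recordings))
    folds = np.array_split(order, k)
    for fold in folds:
        test_idx = set(int(i) for i in fold)
        yield (
            [r for i, r in enumerate(recordings) if i not in test_idx],
            [r for i, r in enumerate(recordings) if i in test_idx],
        )


def _bucket_batches(pairs, batch_size, rng):
    """Group samples by sequence length, then batch within each bucket."""
    buckets: dict[int, list[int]] = {}
    for i, (frames, _) in enumerate(pairs):
        buckets.setdefault(len(frames), []).append(i)
    batches = []
    for idxs in buckets.values():
        idxs = list(rng.permutation(idxs))
        batches += [idxs[i : i + batch_size] for i in range(0, len(idxs), batch_size)]
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _accuracy_on(model, tree, pairs, batch_size=16):
    """(leaf accuracy, root accuracy) of greedy-decoded predictions."""
    from .hierarchy import decode_prediction

    leaf_hits = root_hits = 0
    by_len: dict[int, list[int]] = {}
    for i, (frames, _) in enumerate(pairs):
        by_len.setdefault(len(frames), []).append(i)
    for idxs in by_len.values():
        for lo in range(0, len(idxs), batch_size):
            chunk = idxs[lo : lo + batch_size]
            x = np.stack([pairs[i][0] for i in chunk])
            probs = model.forward(x)
            for i, row in zip(chunk, probs):
                truth = pairs[i][1]
                pred = decode_prediction(tree, row)
                leaf_hits += pred.leaf == truth
                root_hits += pred.root_branch == root_label(tree, truth)
    return leaf_hits / len(pairs), root_hits / len(pairs)


def train(
    model: DRHN,
    train_pairs: list[tuple[np.ndarray, str]],
    config: TrainingConfig,
    aug: AugmentationParams | None = None,
    val_pairs: list[tuple[np.ndarray, str]] | None = None,
    tree: PostureTree | None = None,
    log_csv=None,
    verbose: bool = False,
) -> list[dict]:
    """Adam-optimize the summed BCE over the flattened tree targets.

    Batches are bucketed by sequence length (the recurrent stage defines no
    padding semantics, so mixed-length batches are never formed).  Returns the
    per-epoch history; the model is updated in place.  Divergence (NaN loss)
    aborts with a diagnostic.
    """
    config.validate()
    if not train_pairs:
        raise ValueError("empty training set")
    tree = tree or build_default_tree()
    if model.config.output_units != tree.n_nodes:
        raise ValueError(
            f"model outputs {model.config.output_units} units but the tree has "
            f"{tree.n_nodes} nodes"
        )
    rng = np.random.default_rng(config.seed)
    model._dropout_rng.bit_generator.state = np.random.default_rng(
        config.seed + 1
    ).bit_generator.state
    targets = {leaf: encode_label(tree, leaf) for leaf in tree.leaf_names}
    opt = Adam(model.params(), lr=config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for batch in _bucket_batches(train_pairs, config.batch_size, rng):
            xs, ys = [], []
            for i in batch:
                frames, leaf = train_pairs[i]
                if aug is not None:
                    frames = augment_sequence(frames, aug, rng)
                xs.append(frames)
                ys.append(targets[leaf])
            x = np.stack(xs).astype(np.float32)
            y = np.stack(ys).astype(np.float32)
            probs = model.forward(x, train=True)
            loss = bce_loss(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={config.learning_rate})"
                )
            opt.zero_grad()
            model.backward((probs - y) / len(batch))
            if config.grad_clip_norm is not None:
                total = np.sqrt(sum(float((p.grad**2).sum()) for p in opt.params))
                if total > config.grad_clip_norm:
                    scale = config.grad_clip_norm / total
                    for p in opt.params:
                        p.grad *= scale
            opt.step()
            epoch_loss += loss
            n_batches += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if val_pairs:
            row["val_leaf_acc"], row["val_root_acc"] = _accuracy_on(
                model, tree, val_pairs
            )
        history.append(row)
        if verbose:
            print("  " + "  ".join(f"{k}={v:.4f}" if k != "epoch" else f"{k}={v}"
                                   for k, v in row.items()), flush=True)
    if log_csv is not None and history:
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[-1].keys()))
            writer.writeheader()
            for row in history:
                writer.writerow(row)
    return history
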