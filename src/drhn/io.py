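"""Dataset layout readers/writers.

On disk a recording is a directory of lossless PNG pairs plus sidecar files::

    <root>/<subject>/<recording>/
        rgb_000000.png    8-bit RGB
        depth_000000.png  16-bit grayscale; value/65535 = depth / max range
        labels.csv        columns: frame, label, angle
        meta.yaml         subject id, camera view, fps, generator params

Depth PNGs store the already-normalized depth (clamped at the maximum sensor
range and scaled to the full 16-bit span), so reading is a pure /65535 and
the write/read loop is bit-exact.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .training import Recording

__all__ = [
    "DatasetManifest",
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "build_manifest",
]


@dataclass
class DatasetManifest:
    root: str
    subjects: list[str]
    recordings: list[dict]  # subject, recording, n_frames, label histogram
    meta_checksum: str


def write_recording(rec: Recording, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(rec.frames):
        rgb = np.round(frame[..., :3] * 255.0).astype(np.uint8)
        depth = np.round(frame[..., 3] * 65535.0).astype(np.uint16)
        iio.imwrite(path / f"rgb_{i:06d}.png", rgb)
        iio.imwrite(path / f"depth_{i:06d}.png", depth)
    with open(path / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "label", "angle"])
        for i, lbl in enumerate(rec.labels):
            angle = "" if rec.angles is None else f"{rec.angles[i]:.6f}"
            w.writerow([i, lbl, angle])
    meta = {
        "subject_id": rec.subject_id,
        "camera_view": rec.camera_view,
        "n_frames": len(rec),
        "timestamps": [float(t) for t in rec.timestamps],
        **rec.meta,
    }
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_recording(path) -> Recording:
    path = Path(path)
    meta_file = path / "meta.yaml"
    if not meta_file.exists():
        raise FileNotFoundError(f"not a recording directory (no meta.yaml): {path}")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)

    rgb_files = sorted(path.glob("rgb_*.png"))
    if not rgb_files:
        raise FileNotFoundError(f"no RGB frames found under {path}")
    frames = []
    for rgb_file in rgb_files:
        depth_file = path / rgb_file.name.replace("rgb_", "depth_")
        if not depth_file.exists():
            raise FileNotFoundError(f"missing depth frame: {depth_file}")
        rgb = iio.imread(rgb_file).astype(np.float32) / 255.0
        depth = iio.imread(depth_file).astype(np.float32) / 65535.0
        frames.append(np.dstack([rgb, depth]))
    frames = np.stack(frames)

    labels_file = path / "labels.csv"
    if not labels_file.exists():
        raise FileNotFoundError(f"missing labels.csv under {path}")
    labels, angles = [], []
    with open(labels_file, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "label" not in reader.fieldnames:
            raise ValueError(f"malformed labels.csv (no 'label' column): {labels_file}")
        for row in reader:
            labels.append(row["label"])
            angles.append(float(row["angle"]) if row.get("angle") else np.nan)
    if len(labels) != len(frames):
        raise ValueError(
            f"label/frame mismatch under {path}: "
            f"{len(labels)} labels vs {len(frames)} frame pairs"
        )
    ts = meta.get("timestamps")
    if ts is None or len(ts) != len(frames):
        ts = np.arange(len(frames), dtype=np.float64)
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("subject_id", "camera_view", "timestamps", "n_frames")
    }
    angles_arr = np.asarray(angles, dtype=np.float64)
    return Recording(
        subject_id=meta["subject_id"],
        camera_view=meta["camera_view"],
        frames=frames,
        labels=labels,
        timestamps=np.asarray(ts, dtype=np.float64),
        angles=None if np.all(np.isnan(angles_arr)) else angles_arr,
        meta=extra,
    )


def write_dataset(recordings: list[Recording], root) -> Path:
    """Write recordings as ``<root>/<subject>/<recNNN_stage>/``."""
    root = Path(root)
    counters: dict[str, int] = {}
    for rec in recordings:
        i = counters.get(rec.subject_id, 0)
        counters[rec.subject_id] = i + 1
        stage = rec.meta.get("stage", "rec")
        write_recording(rec, root / rec.subject_id / f"rec{i:03d}_{stage}")
    return root


def read_dataset(root) -> list[Recording]:
    root = Path(root)
    recs = []
    for meta_file in sorted(root.glob("*/*/meta.yaml")):
        recs.append(read_recording(meta_file.parent))
    if not recs:
        raise FileNotFoundError(f"no recordings found under {root}")
    return recs


def build_manifest(root) -> DatasetManifest:
    root = Path(root)
    recs, subjects = [], set()
    digest = hashlib.sha256()
    for meta_file in sorted(root.glob("*/*/meta.yaml")):
        digest.update(meta_file.read_bytes())
        rec_dir = meta_file.parent
        rgb = sorted(rec_dir.glob("rgb_*.png"))
        depth = sorted(rec_dir.glob("depth_*.png"))
        if len(rgb) != len(depth):
            raise ValueError(
                f"RGB/depth count mismatch in {rec_dir}: {len(rgb)} vs {len(depth)}"
            )
        hist: dict[str, int] = {}
        with open(rec_dir / "labels.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                hist[row["label"]] = hist.get(row["label"], 0) + 1
        subjects.add(rec_dir.parent.name)
        recs.append(
            {
                "subject": rec_dir.parent.name,
                "recording": rec_dir.name,
                "n_frames": len(rgb),
                "labels": hist,
            }
        )
    return DatasetManifest(
        root=str(root),
        subjects=sorted(subjects),
        recordings=recs,
        meta_checksum=digest.hexdigest(),
    )
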