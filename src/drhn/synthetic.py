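"""Synthetic seated-posture RGB-D recordings.

Emulates the capture protocol behind the posture dataset: a subject sits at
a desk; a depth camera films from one of three viewpoints (10, 12 or
3 o'clock); the desk hides roughly the lower 70% of the body, so only the
upper torso and head are visible.  A latent *spine angle* drives posture:
0 rad is sitting straight, negative angles hunch forward in three grades,
positive angles recline backward (partially lying, then lying down).

Two scripted recordings per subject and view:

* **Stage I** — eight consecutive 30 s constant-angle segments (straight,
  three forward grades, straight again, three backward grades; the two worst
  backward grades both carry the "lying down" label).
* **Stage II** — five continuous straight-to-worst-forward-and-back sweeps,
  then five backward sweeps, linear in angle.

Rendering is a deliberately simple 2-D articulated silhouette: a torso
capsule rotated by the spine angle with an attached head disc, composited
behind a desk rectangle, over a far background.  The depth channel encodes
body/desk/background ordering with Gaussian sensor noise, 16-bit
quantization and random dropout near depth edges.  Every frame's label is
recomputable from its stored latent angle, so the generator can never emit
inconsistent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .training import Recording

__all__ = [
    "SubjectParams",
    "SceneParams",
    "LabelThresholds",
    "angle_to_label",
    "render_frame",
    "generate_stage1",
    "generate_stage2",
    "generate_cohort",
    "STAGE1_ANGLES",
    "VIEWS",
]

VIEWS = ("10 o'clock", "12 o'clock", "3 o'clock")

# nominal spine angles (rad) of the eight Stage I segments:
# straight, 3 forward grades, straight, 3 backward grades
STAGE1_ANGLES = (0.0, -0.14, -0.28, -0.45, 0.0, 0.20, 0.38, 0.55)

# view -> (horizontal mirror, fraction of the spine angle expressed as
# horizontal lean).  The 12 o'clock (frontal) view shows hunching mostly as
# a vertical head drop plus a depth change, not a lateral shift.
_VIEW_GEOMETRY = {
    "10 o'clock": (True, 0.9),
    "12 o'clock": (False, 0.25),
    "3 o'clock": (False, 1.0),
}


@dataclass
class LabelThresholds:
    """Angle cuts (rad) partitioning the spine-angle range into the 6 labels."""

    straight_band: float = 0.08
    forward_cut_1: float = -0.20   # lightly hunched / hunched over
    forward_cut_2: float = -0.35   # hunched over / extremely hunched
    backward_cut: float = 0.30     # partially lying / lying down


@dataclass
class SubjectParams:
    """Anthropometry and appearance of one synthetic subject (pixels)."""

    torso_length: float
    head_radius: float
    shoulder_width: float
    seat_height: float
    baseline_slouch: float = 0.0  # habitual forward lean, |.| <= 0.15 rad
    skin_color: tuple = (0.85, 0.70, 0.60)
    clothing_color: tuple = (0.25, 0.35, 0.55)

    def __post_init__(self):
        if min(self.torso_length, self.head_radius, self.shoulder_width,
               self.seat_height) <= 0:
            raise ValueError("all subject dimensions must be positive")
        if abs(self.baseline_slouch) > 0.15:
            raise ValueError("baseline_slouch must satisfy |.| <= 0.15 rad")


@dataclass
class SceneParams:
    """Camera viewpoint, desk occlusion and depth-sensor characteristics."""

    camera_view: str = "3 o'clock"
    desk_occlusion_fraction: float = 0.7
    image_size: tuple[int, int] = (48, 64)  # (H, W)
    depth_noise_sd: float = 0.01            # in normalized [0,1] depth units
    edge_dropout_p: float = 0.02
    body_depth_m: float = 1.2
    desk_depth_m: float = 0.9
    background_depth_m: float = 3.0
    depth_max_range_m: float = 4.0

    def __post_init__(self):
        if self.camera_view not in _VIEW_GEOMETRY:
            raise ValueError(f"unknown camera view: {self.camera_view!r}")
        if not 0.0 <= self.desk_occlusion_fraction < 1.0:
            raise ValueError("desk_occlusion_fraction must be in [0, 1)")


def angle_to_label(angle: float, thresholds: LabelThresholds | None = None) -> str:
    """Monotone step mapping from spine angle to the six posture labels.

    Decreasing (more negative, forward) angles step through sitting straight
    -> lightly hunched -> hunched over -> extremely hunched; increasing
    angles through partially lying -> lying down.
    """
    t = thresholds or LabelThresholds()
    if not -np.pi / 2 <= angle <= np.pi / 2:
        raise ValueError(f"spine angle {angle} outside [-pi/2, pi/2]")
    if angle > t.backward_cut:
        return "lying down"
    if angle > t.straight_band:
        return "partially lying"
    if angle >= -t.straight_band:
        return "sitting straight"
    if angle >= t.forward_cut_1:
        return "lightly hunched"
    if angle >= t.forward_cut_2:
        return "hunched over"
    return "extremely hunched"


def _capsule_mask(yy, xx, p0, p1, radius):
    """Pixels within ``radius`` of the segment p0-p1 (capsule / thick line)."""
    d = np.array(p1) - np.array(p0)
    L2 = float(d @ d)
    if L2 == 0:
        t = np.zeros_like(yy, dtype=np.float64)
    else:
        t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / L2, 0.0, 1.0)
    cx = p0[0] + t * d[0]
    cy = p0[1] + t * d[1]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def render_frame(
    subject: SubjectParams,
    scene: SceneParams,
    angle: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One (H, W, 4) float32 RGB-D frame of the subject at a spine angle.

    Depth is normalized to [0, 1] by ``depth_max_range_m`` and 16-bit
    quantized; identical rng state yields bit-identical frames.
    """
    if not -np.pi / 2 <= angle <= np.pi / 2:
        raise ValueError(f"spine angle {angle} outside [-pi/2, pi/2]")
    H, W = scene.image_size
    mirror, lean_gain = _VIEW_GEOMETRY[scene.camera_view]
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    # hip anchor; forward lean moves the upper body toward the desk side (+x)
    hip = (0.45 * W, H - subject.seat_height)
    eff = angle  # signed; negative = forward
    dx = np.sin(-eff) * lean_gain  # forward (neg angle) -> +x
    dy = -np.cos(eff)
    neck = (hip[0] + subject.torso_length * dx, hip[1] + subject.torso_length * dy)
    head_c = (
        neck[0] + (subject.head_radius * 1.2) * dx,
        neck[1] + (subject.head_radius * 1.2) * dy,
    )
    torso = _capsule_mask(yy, xx, hip, neck, subject.shoulder_width / 2.0)
    head = (xx - head_c[0]) ** 2 + (yy - head_c[1]) ** 2 <= subject.head_radius**2

    # desk top placed so the lower desk_occlusion_fraction of the straight
    # body span (hip to head top) is hidden
    span = subject.torso_length + 2.4 * subject.head_radius
    desk_top = hip[1] - scene.desk_occlusion_fraction * span
    desk = yy >= desk_top

    rgb = np.empty((H, W, 3))
    rgb[:] = (0.55, 0.55, 0.60)  # wall
    rgb[torso] = subject.clothing_color
    rgb[head] = subject.skin_color
    rgb[desk] = (0.45, 0.33, 0.22)

    # leaning toward (away from) the camera brings the body nearer (farther);
    # strongest in the frontal view where the lateral shift is weakest
    depth_gain = 0.35 * (1.0 - lean_gain) + 0.1
    body_depth = scene.body_depth_m + depth_gain * np.sin(eff)
    depth = np.full((H, W), scene.background_depth_m)
    depth[torso | head] = body_depth
    depth[desk] = scene.desk_depth_m

    if mirror:
        rgb = rgb[:, ::-1]
        depth = depth[:, ::-1]

    # sensor model: Gaussian noise, 16-bit quantization, edge dropout
    d = np.clip(depth / scene.depth_max_range_m, 0.0, 1.0)
    if scene.depth_noise_sd > 0:
        d = d + rng.normal(0.0, scene.depth_noise_sd, d.shape)
    d = np.round(np.clip(d, 0.0, 1.0) * 65535.0) / 65535.0
    if scene.edge_dropout_p > 0:
        gy, gx = np.gradient(depth)
        edges = np.hypot(gy, gx) > 0.05
        drop = edges & (rng.random(d.shape) < 0.5) | (
            rng.random(d.shape) < scene.edge_dropout_p
        )
        d[drop] = 0.0

    rgb = np.clip(rgb + rng.normal(0.0, 0.01, rgb.shape), 0.0, 1.0)
    rgb = np.round(rgb * 255.0) / 255.0  # 8-bit sensor quantization

    frame = np.empty((H, W, 4), dtype=np.float32)
    frame[..., :3] = rgb
    frame[..., 3] = d
    return frame


def _record(subject, scene, angles, rng, fps, subject_id, stage):
    frames = np.stack(
        [render_frame(subject, scene, a, rng) for a in angles]
    )
    labels = [angle_to_label(a) for a in angles]
    return Recording(
        subject_id=subject_id,
        camera_view=scene.camera_view,
        frames=frames,
        labels=labels,
        timestamps=np.arange(len(angles)) / fps,
        angles=np.asarray(angles, dtype=np.float64),
        meta={"stage": stage, "fps": fps},
    )


def generate_stage1(
    subject: SubjectParams,
    scene: SceneParams,
    rng: np.random.Generator,
    fps: float = 1.0,
    segment_s: float = 30.0,
    subject_id: str = "s00",
) -> Recording:
    """Eight constant-angle 30 s segments (straight, 3 forward, straight,
    3 backward); per-frame labels derive from the segment angle plus the
    subject's habitual slouch."""
    per_seg = max(1, int(round(segment_s * fps)))
    angles = []
    for nominal in STAGE1_ANGLES:
        a = float(np.clip(nominal + subject.baseline_slouch, -np.pi / 2, np.pi / 2))
        angles += [a] * per_seg
    return _record(subject, scene, angles, rng, fps, subject_id, "stage1")


def generate_stage2(
    subject: SubjectParams,
    scene: SceneParams,
    rng: np.random.Generator,
    fps: float = 1.0,
    count_s: float = 5.0,
    sweeps_per_direction: int = 5,
    apex_forward: float = -0.50,
    apex_backward: float = 0.55,
    subject_id: str = "s00",
) -> Recording:
    """Continuous worsening sweeps: straight -> apex -> straight, linear in
    angle, five times forward then five times backward."""
    per_leg = max(2, int(round(count_s * fps)))
    angles = []
    for apex in (apex_forward, apex_backward):
        leg = np.linspace(0.0, apex, per_leg, endpoint=True)
        cycle = np.concatenate([leg, leg[::-1][1:]])
        for _ in range(sweeps_per_direction):
            angles.extend(
                float(np.clip(a + subject.baseline_slouch, -np.pi / 2, np.pi / 2))
                for a in cycle
            )
    return _record(subject, scene, angles, rng, fps, subject_id, "stage2")


def draw_subject(
    rng: np.random.Generator,
    image_size: tuple[int, int] = (48, 64),
    baseline_slouch_sd: float = 0.0,
) -> SubjectParams:
    """Sample one subject's anthropometry, scaled to the image height.

    ``baseline_slouch_sd = 0`` (the default) produces unambiguous labels;
    a positive value reproduces the habitual-posture labelling ambiguity
    seen in real cohorts.
    """
    H = image_size[0]
    slouch = float(np.clip(rng.normal(0.0, baseline_slouch_sd), -0.15, 0.15)) \
        if baseline_slouch_sd > 0 else 0.0
    return SubjectParams(
        torso_length=max(4.0, rng.normal(0.45, 0.03) * H),
        head_radius=max(2.0, rng.normal(0.11, 0.01) * H),
        shoulder_width=max(2.0, rng.normal(0.16, 0.015) * H),
        seat_height=max(1.0, rng.normal(0.14, 0.02) * H),
        baseline_slouch=slouch,
        skin_color=tuple(np.clip(
            np.array([0.85, 0.70, 0.60]) + rng.normal(0, 0.05, 3), 0.05, 1.0)),
        clothing_color=tuple(rng.uniform(0.1, 0.9, 3)),
    )


def generate_cohort(
    n_subjects: int = 11,
    views: tuple[str, ...] = VIEWS,
    seed: int = 0,
    image_size: tuple[int, int] = (48, 64),
    fps: float = 1.0,
    segment_s: float = 30.0,
    count_s: float = 5.0,
    baseline_slouch_sd: float = 0.0,
    depth_noise_sd: float = 0.01,
    edge_dropout_p: float = 0.02,
) -> list[Recording]:
    """Full synthetic study: per subject, Stage I + Stage II at every view.

    11 subjects x 3 views gives 66 recordings, mirroring the original
    capture campaign; fully reproducible from the seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.default_rng(seed)
    recordings: list[Recording] = []
    for si in range(n_subjects):
        subject = draw_subject(root, image_size, baseline_slouch_sd)
        sid = f"s{si:02d}"
        for view in views:
            scene = SceneParams(
                camera_view=view,
                image_size=image_size,
                depth_noise_sd=depth_noise_sd,
                edge_dropout_p=edge_dropout_p,
            )
            rec_rng = np.random.default_rng(root.integers(2**31))
            recordings.append(
                generate_stage1(subject, scene, rec_rng, fps, segment_s, sid)
            )
            recordings.append(
                generate_stage2(
                    subject, scene, rec_rng, fps, count_s, subject_id=sid
                )
            )
    return recordings
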