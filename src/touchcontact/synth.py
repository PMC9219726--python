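"""Synthetic forearm surfaces and gesture trials with analytic ground truth.

The generator emulates the measurement scenario: a half-cylindrical
forearm point cloud (the upper surface a camera would see) and a rigid
hand footprint — a patch of mesh vertices conformal to the arm surface —
executing one of the four social-touch gestures (stroke, tap, hold,
shake) at 30 Hz. Every trial records the programmed per-frame velocity
components, indentation, contact window and footprint area, so the
measurement pipeline can be validated against known truth.

Gesture laws
------------
stroke : back-and-forth longitudinal sweeps at constant speed with
    constant indentation. Sweep turnarounds coincide with sample
    instants so raw finite differences recover the programmed speed.
tap : smooth vertical dips at ``repetition_rate``; the patch penetrates
    to ``indentation_amplitude`` for roughly a third of each cycle and
    lifts clear of the skin in between.
hold : static indentation for the whole trial.
shake : band-limited random tangential velocity (longitudinal and
    lateral) with a small vertical wobble, contact maintained throughout.

Positional noise emulates tracking jitter: a temporally smoothed
(low-frequency) Gaussian offset of standard deviation ``noise_sd``
applied rigidly to the hand mesh and joint per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .cloud import M_TO_CM, M_TO_MM, M2_TO_CM2, ArmSurface, HandMeshFrame, SurfacePointCloud
from .kinematics import DEFAULT_CAMERA_RATE

__all__ = [
    "GestureConfig",
    "SyntheticTrial",
    "FOOTPRINT_AREAS_CM2",
    "make_forearm",
    "simulate_gesture",
    "default_gesture_config",
    "make_trial_batch",
    "make_tabletop_scene",
    "GESTURES",
]

GESTURES = ("stroke", "tap", "hold", "shake")

#: Target contact scale of each hand footprint, cm².
FOOTPRINT_AREAS_CM2 = {"fingertip": 2.0, "finger_pad": 10.0, "full_hand": 30.0}

_DEFAULT_FOOTPRINT = {
    "stroke": "finger_pad",
    "tap": "fingertip",
    "hold": "full_hand",
    "shake": "full_hand",
}
_DEFAULT_SPEED = {"stroke": 10.0, "tap": 0.0, "hold": 0.0, "shake": 8.0}


@dataclass
class GestureConfig:
    """Parameters of one simulated touch trial.

    speed_amplitude is cm/s (stroke sweep speed; shake RMS tangential
    speed), indentation_amplitude mm, repetition_rate Hz (tap dips),
    noise_sd mm of tracking jitter. ``seed`` fixes all randomness.
    """

    gesture: str
    speed_amplitude: float = 10.0
    indentation_amplitude: float = 3.0
    footprint: str = "finger_pad"
    repetition_rate: float = 3.0
    total_duration: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0
    sampling_rate: float = DEFAULT_CAMERA_RATE
    patch_spacing: float = 0.002

    def __post_init__(self) -> None:
        if self.gesture not in GESTURES:
            raise ValueError(f"gesture must be one of {GESTURES}")
        if self.footprint not in FOOTPRINT_AREAS_CM2:
            raise ValueError(f"footprint must be one of {tuple(FOOTPRINT_AREAS_CM2)}")
        if self.speed_amplitude < 0 or self.indentation_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")


def default_gesture_config(gesture: str, seed: int = 0, **overrides) -> GestureConfig:
    """Gesture-typical defaults: strokes with the finger pad at 10 cm/s,
    taps with the fingertip at 3 Hz, holds and shakes with the full hand."""
    params = dict(
        gesture=gesture,
        footprint=_DEFAULT_FOOTPRINT[gesture],
        speed_amplitude=_DEFAULT_SPEED[gesture],
        seed=seed,
    )
    params.update(overrides)
    return GestureConfig(**params)


@dataclass
class SyntheticTrial:
    """A simulated trial: the arm, the hand frames and the programmed truth."""

    arm: ArmSurface
    hand_frames: list
    truth: pd.DataFrame
    config: GestureConfig = None


def make_forearm(
    radius: float = 0.04,
    length: float = 0.25,
    spacing: float = 0.002,
    *,
    skin_color=(0.85, 0.65, 0.55),
) -> ArmSurface:
    """Upper half-cylinder forearm sampled on a surface grid.

    The cylinder axis runs along the longitudinal (+y, elbow at -y) at
    z = 0; the top of the arm sits at z = radius. Normals are analytic
    outward radials; the marker anchor is placed on top of the elbow end.
    """
    if not (0 < spacing < radius / 4):
        raise ValueError("spacing must be positive and smaller than radius/4")
    if length <= 0 or radius <= 0:
        raise ValueError("radius and length must be positive")
    n_theta = max(int(round(np.pi * radius / spacing)) + 1, 4)
    n_y = max(int(round(length / spacing)) + 1, 2)
    theta = np.linspace(0.0, np.pi, n_theta)
    ys = np.linspace(-length / 2, length / 2, n_y)
    tt, yy = np.meshgrid(theta, ys, indexing="ij")
    pts = np.column_stack(
        [radius * np.cos(tt).ravel(), yy.ravel(), radius * np.sin(tt).ravel()]
    )
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.zeros(tt.size), np.sin(tt).ravel()]
    )
    colors = np.tile(np.asarray(skin_color, dtype=float), (len(pts), 1))
    cloud = SurfacePointCloud(points=pts, colors=colors, normals=normals)
    anchor = np.array([0.0, -length / 2, radius])
    return ArmSurface.from_cloud(cloud, marker_anchor=anchor)


def _conformal_patch(radius: float, area_cm2: float, spacing: float):
    """Vertex patch conformal to a cylinder of given radius around its top.

    Parameterized by arc offset (lateral) and axial offset (longitudinal);
    the footprint is ~1.5x longer along the arm than across it.
    """
    area = area_cm2 / M2_TO_CM2
    width = np.sqrt(area / 1.5)  # arc extent
    length = 1.5 * width
    max_arc = 0.9 * np.pi * radius
    if width > max_arc:
        raise ValueError("footprint larger than the arm's circumference")
    n_a = max(int(round(width / spacing)) + 1, 2)
    n_y = max(int(round(length / spacing)) + 1, 2)
    arc = np.linspace(-width / 2, width / 2, n_a)
    ax = np.linspace(-length / 2, length / 2, n_y)
    aa, yy = np.meshgrid(arc, ax, indexing="ij")
    return aa.ravel(), yy.ravel(), length


def _smoothed_noise(rng, n: int, sigma_frames: float = 3.0) -> np.ndarray:
    """Unit-variance low-frequency Gaussian noise of length n."""
    x = gaussian_filter1d(rng.standard_normal(n + 40), sigma_frames)[20:-20]
    s = x.std()
    return x / s if s > 0 else x


def simulate_gesture(config: GestureConfig, arm: ArmSurface | None = None) -> SyntheticTrial:
    """Simulate one trial of the configured gesture against the arm.

    Truth channels (programmed law, before noise) use the reporting units
    of the pipeline: velocities cm/s, depth mm, area cm².
    """
    if arm is None:
        arm = make_forearm()
    # infer cylinder geometry from the arm cloud (top height = radius)
    radius = float(arm.cloud.points[:, 2].max())
    y_lo = float(arm.cloud.points[:, 1].min())
    y_hi = float(arm.cloud.points[:, 1].max())

    f = config.sampling_rate
    n = int(round(config.total_duration * f))
    if n < 2:
        raise ValueError("total_duration too short for two frames")
    t = np.arange(n) / f
    rng = np.random.default_rng(config.seed)

    amp = config.indentation_amplitude / M_TO_MM  # metres
    arc_off, ax_off, patch_len = _conformal_patch(
        radius, FOOTPRINT_AREAS_CM2[config.footprint], config.patch_spacing
    )

    y_c = np.zeros(n)          # longitudinal centre
    x_c = np.zeros(n)          # lateral translation
    radial = np.full(n, -amp)  # patch offset from skin: negative = indented

    if config.gesture == "stroke":
        v = config.speed_amplitude / M_TO_CM  # m/s
        sweep_frames = max(int(round(0.5 * f)), 1)
        sweep_len = v * sweep_frames / f
        if sweep_len + patch_len > (y_hi - y_lo):
            raise ValueError("stroke sweep exceeds the arm length")
        # triangle wave with apexes exactly on sample instants
        phase = (np.arange(n) % (2 * sweep_frames)) / sweep_frames
        tri = np.where(phase <= 1.0, phase, 2.0 - phase)  # in [0, 1]
        y_c = (tri - 0.5) * sweep_len
    elif config.gesture == "tap":
        s = np.sin(2 * np.pi * config.repetition_rate * t)
        c = 0.5
        radial = -amp * (s - c) / (1 - c)  # >0 above skin, <0 indented
    elif config.gesture == "hold":
        pass
    elif config.gesture == "shake":
        v_target = config.speed_amplitude / M_TO_CM / np.sqrt(2)  # per axis
        for arr in (x_c, y_c):
            pos = _smoothed_noise(rng, n)
            vel_rms = np.sqrt(np.mean((np.diff(pos) * f) ** 2))
            arr[:] = pos * (v_target / vel_rms) if vel_rms > 0 else 0.0
        wobble = _smoothed_noise(rng, n)
        radial = -amp * (1.0 + 0.3 * np.clip(wobble, -1, 1))

    depth_m = np.maximum(0.0, -radial)
    contact = depth_m > 0
    footprint_cm2 = FOOTPRINT_AREAS_CM2[config.footprint]

    # programmed velocities (cm/s): finite differences of the law at the
    # camera instants, which is what a 30 Hz tracker can at best observe
    def backward_diff(x):
        d = np.zeros(n)
        d[1:] = np.diff(x) * f
        return d

    v_lg = backward_diff(y_c) * M_TO_CM
    v_lt = backward_diff(x_c) * M_TO_CM
    v_vt = backward_diff(radial) * M_TO_CM
    v_abs = np.sqrt(v_lg**2 + v_lt**2 + v_vt**2)

    truth = pd.DataFrame(
        {
            "t": t,
            "contact": contact.astype(int),
            "Vabs": v_abs,
            "Vlg": v_lg,
            "Vlt": v_lt,
            "Vvt": v_vt,
            "area": np.where(contact, footprint_cm2, 0.0),
            "depth": depth_m * M_TO_MM,
        }
    )

    # rigid low-frequency tracking jitter
    jitter = np.zeros((n, 3))
    if config.noise_sd > 0:
        sd = config.noise_sd / M_TO_MM
        jitter = np.column_stack([_smoothed_noise(rng, n) * sd for _ in range(3)])

    frames = []
    for i in range(n):
        r = radius + radial[i]
        th = np.pi / 2 + arc_off / radius
        verts = np.column_stack(
            [r * np.cos(th) + x_c[i], ax_off + y_c[i], r * np.sin(th)]
        )
        joint = np.array([x_c[i], y_c[i], radius + radial[i] + 0.02])
        frames.append(
            HandMeshFrame(
                vertices=verts + jitter[i],
                joint_position=joint + jitter[i],
                timestamp=t[i],
            )
        )
    return SyntheticTrial(arm=arm, hand_frames=frames, truth=truth, config=config)


def make_trial_batch(
    n_per_gesture: int,
    seed: int = 0,
    arm: ArmSurface | None = None,
    vary: float = 0.2,
    gestures=GESTURES,
    **overrides,
) -> list[SyntheticTrial]:
    """A balanced batch of trials with natural inter-trial variability.

    Each trial starts from the gesture defaults and perturbs speed,
    indentation, repetition rate and duration by up to ``vary`` (uniform,
    relative), emulating how human touchers vary their delivery across
    repeats; ``vary=0`` reproduces the defaults exactly. Trial seeds are
    derived from ``seed`` so the batch is reproducible as a whole.
    """
    if arm is None:
        arm = make_forearm()
    rng = np.random.default_rng(seed)
    trials = []
    for gesture in gestures:
        for _ in range(n_per_gesture):
            cfg = default_gesture_config(
                gesture, seed=int(rng.integers(0, 2**31 - 1)), **overrides
            )
            if vary > 0:
                u = lambda: 1.0 + rng.uniform(-vary, vary)
                cfg = GestureConfig(
                    gesture=cfg.gesture,
                    speed_amplitude=cfg.speed_amplitude * u(),
                    indentation_amplitude=cfg.indentation_amplitude * u(),
                    footprint=cfg.footprint,
                    repetition_rate=cfg.repetition_rate * u(),
                    total_duration=cfg.total_duration * u(),
                    noise_sd=cfg.noise_sd,
                    seed=cfg.seed,
                    sampling_rate=cfg.sampling_rate,
                    patch_spacing=cfg.patch_spacing,
                )
            trials.append(simulate_gesture(cfg, arm))
    return trials


def make_tabletop_scene(
    mode: str = "plane",
    seed: int = 0,
    *,
    arm_spacing: float = 0.0025,
):
    """Synthetic colored capture scene for segmentation tests.

    A forearm half-cylinder (skin colored, with a blue marker patch near
    the elbow) rests 1.5 cm above a supporting surface — a gray table
    (``mode='plane'``) or a monochromatic green cushion
    (``mode='color'``) — plus a few small debris blobs. Returns
    ``(scene, labels)`` with labels 0 = background, 1 = forearm
    (marker included), 2 = debris.
    """
    if mode not in ("plane", "color"):
        raise ValueError("mode must be 'plane' or 'color'")
    rng = np.random.default_rng(seed)

    # supporting surface at z = 0 with sub-mm sensor noise
    nx, ny = 80, 80
    gx, gy = np.meshgrid(
        np.linspace(-0.2, 0.2, nx), np.linspace(-0.2, 0.2, ny), indexing="ij"
    )
    table = np.column_stack(
        [gx.ravel(), gy.ravel(), rng.normal(0, 0.0005, nx * ny)]
    )
    if mode == "plane":
        bg_color = np.array([0.50, 0.50, 0.48])
    else:
        bg_color = np.array([0.20, 0.70, 0.25])  # green cushion
    table_colors = bg_color + rng.normal(0, 0.02, table.shape)

    # forearm raised above the support
    arm = make_forearm(radius=0.04, length=0.25, spacing=arm_spacing)
    arm_pts = arm.cloud.points + np.array([0.0, 0.0, 0.015])
    arm_pts = arm_pts + rng.normal(0, 0.0002, arm_pts.shape)
    arm_colors = np.array([0.85, 0.65, 0.55]) + rng.normal(0, 0.02, arm_pts.shape)
    # blue marker patch on top of the elbow end
    marker = (
        (arm_pts[:, 1] < -0.09)
        & (arm_pts[:, 1] > -0.11)
        & (arm_pts[:, 2] > 0.04)
    )
    arm_colors[marker] = np.array([0.15, 0.25, 0.85]) + rng.normal(
        0, 0.02, (marker.sum(), 3)
    )

    # sparse debris blobs well away from the arm
    debris = []
    for centre in ([0.15, 0.15, 0.10], [-0.15, -0.12, 0.12], [0.12, -0.15, 0.08]):
        debris.append(np.asarray(centre) + rng.normal(0, 0.004, (20, 3)))
    debris = np.vstack(debris)
    debris_colors = rng.uniform(0.3, 0.9, debris.shape)

    points = np.vstack([table, arm_pts, debris])
    colors = np.clip(np.vstack([table_colors, arm_colors, debris_colors]), 0, 1)
    labels = np.concatenate(
        [np.zeros(len(table), int), np.ones(len(arm_pts), int),
         np.full(len(debris), 2)]
    )
    return SurfacePointCloud(points=points, colors=colors), labels
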