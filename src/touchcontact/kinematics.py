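"""Arm coordinate frame, hand velocity decomposition and attribute series.

The arm coordinate is a right-handed orthonormal triad anchored on the
receiver's forearm: the vertical axis ``i_vt`` points up (the outward
normal of a horizontal surface or of the top of the forearm), the
longitudinal axis ``i_lg`` points from elbow to wrist and is obtained by
projecting the camera y-axis onto the plane perpendicular to ``i_vt``
(the forearm is recorded parallel to the image y-axis), and the lateral
axis closes the triad, ``i_lt = i_lg x i_vt``.

Hand velocity is the raw finite difference of the tracked reference-joint
position over consecutive frames — no smoothing — decomposed onto the
triad and reported in cm/s. Contact duration is the number of in-contact
frames divided by the camera rate (30 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud import M_TO_CM, ArmSurface, HandMeshFrame
from .contact import measure_contact

__all__ = [
    "ArmFrame",
    "ContactAttributeSeries",
    "build_arm_frame",
    "decompose_velocity",
    "contact_duration",
    "compute_series",
    "vertical_from_arm_top",
]

DEFAULT_CAMERA_RATE = 30.0


@dataclass
class ArmFrame:
    """Right-handed orthonormal arm coordinate triad."""

    i_vt: np.ndarray
    i_lg: np.ndarray
    i_lt: np.ndarray
    camera_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("i_vt", "i_lg", "i_lt", "camera_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


def build_arm_frame(vertical_normal, camera_y=(0.0, 1.0, 0.0)) -> ArmFrame:
    """Construct the arm triad from a vertical normal and the camera y-axis.

    ``i_lg`` is the unit projection of ``camera_y`` onto the plane
    perpendicular to the vertical axis; ``i_lt = i_lg x i_vt`` closes the
    right-handed triad.

    Raises
    ------
    ValueError
        If the projection degenerates (camera y parallel to the vertical).
    """
    v = np.asarray(vertical_normal, dtype=float)
    y = np.asarray(camera_y, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("vertical_normal must be nonzero")
    i_vt = v / nv
    proj = y - (y @ i_vt) * i_vt
    norm = np.linalg.norm(proj)
    if norm < 1e-8:
        raise ValueError("degenerate longitudinal axis: camera y parallel to vertical")
    i_lg = proj / norm
    i_lt = np.cross(i_lg, i_vt)
    return ArmFrame(i_vt=i_vt, i_lg=i_lg, i_lt=i_lt, camera_y=y)


def vertical_from_arm_top(arm: ArmSurface, quantile: float = 0.95) -> np.ndarray:
    """Estimate the vertical as the mean normal over the arm's topmost points.

    Convenience for scenes without a reference table plane: averages the
    outward normals of points whose height is above the given quantile.
    """
    z = arm.cloud.points[:, 2]
    top = z >= np.quantile(z, quantile)
    n = arm.cloud.normals[top].mean(axis=0)
    return n / np.linalg.norm(n)


def decompose_velocity(p_now, p_prev, dt: float, frame: ArmFrame):
    """Velocity magnitude and its three arm-frame components, in cm/s."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = (np.asarray(p_now, float) - np.asarray(p_prev, float)) / dt * M_TO_CM
    return (
        float(np.linalg.norm(v)),
        float(v @ frame.i_vt),
        float(v @ frame.i_lg),
        float(v @ frame.i_lt),
    )


def contact_duration(contact_flags, f: float = DEFAULT_CAMERA_RATE) -> float:
    """Total contacted time: in-contact frame count over the camera rate."""
    if f <= 0:
        raise ValueError("camera rate f must be positive")
    flags = np.asarray(contact_flags, dtype=bool)
    return float(flags.sum() / f)


@dataclass
class ContactAttributeSeries:
    """Per-trial time series of the six contact attributes plus duration.

    Channels are rectangular (equal length). Velocities are cm/s, area
    cm², depth mm. ``velocity_valid`` marks frames with a defined backward
    difference (the first frame's velocity is reported as 0 and flagged
    invalid rather than dropped, keeping channels aligned with contact
    flags).
    """

    timestamps: np.ndarray
    contact_flags: np.ndarray
    v_abs: np.ndarray
    v_vt: np.ndarray
    v_lg: np.ndarray
    v_lt: np.ndarray
    area: np.ndarray
    depth: np.ndarray
    sampling_rate: float = DEFAULT_CAMERA_RATE
    velocity_valid: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = {
            "timestamps": float, "contact_flags": bool, "v_abs": float,
            "v_vt": float, "v_lg": float, "v_lt": float, "area": float,
            "depth": float,
        }
        n = None
        for name, dtype in arrays.items():
            arr = np.asarray(getattr(self, name), dtype=dtype)
            setattr(self, name, arr)
            if n is None:
                n = len(arr)
            elif len(arr) != n:
                raise ValueError("all channels must have equal length")
        if self.velocity_valid is None:
            self.velocity_valid = np.ones(n, dtype=bool)
        else:
            self.velocity_valid = np.asarray(self.velocity_valid, dtype=bool)
            if len(self.velocity_valid) != n:
                raise ValueError("velocity_valid must match channel length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Contact duration in seconds (flag count / sampling rate)."""
        return contact_duration(self.contact_flags, self.sampling_rate)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.timestamps,
                "contact": self.contact_flags.astype(int),
                "Vabs": self.v_abs,
                "Vlg": self.v_lg,
                "Vlt": self.v_lt,
                "Vvt": self.v_vt,
                "area": self.area,
                "depth": self.depth,
            }
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sampling_rate: float = DEFAULT_CAMERA_RATE, **meta
    ) -> "ContactAttributeSeries":
        valid = np.ones(len(df), dtype=bool)
        if len(df):
            valid[0] = False
        return cls(
            timestamps=df["t"].to_numpy(),
            contact_flags=df["contact"].to_numpy().astype(bool),
            v_abs=df["Vabs"].to_numpy(),
            v_lg=df["Vlg"].to_numpy(),
            v_lt=df["Vlt"].to_numpy(),
            v_vt=df["Vvt"].to_numpy(),
            area=df["area"].to_numpy(),
            depth=df["depth"].to_numpy(),
            sampling_rate=sampling_rate,
            velocity_valid=valid,
            metadata=meta,
        )


def compute_series(
    hand_frames,
    arm: ArmSurface,
    frame: ArmFrame,
    f: float = DEFAULT_CAMERA_RATE,
    *,
    count: str = "arm",
    disc_constant: float = 3.0,
) -> ContactAttributeSeries:
    """Run contact detection and velocity decomposition over a trial.

    Velocities use measured timestamp differences between consecutive
    frames (the nominal rate ``f`` is used only for duration); the first
    frame's velocity is zero and flagged invalid.

    Raises
    ------
    ValueError
        For fewer than 2 frames or non-increasing timestamps.
    """
    hand_frames = list(hand_frames)
    if len(hand_frames) < 2:
        raise ValueError("compute_series requires >= 2 frames")
    ts = np.array([h.timestamp for h in hand_frames], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    n = len(hand_frames)
    flags = np.zeros(n, dtype=bool)
    area = np.zeros(n)
    depth = np.zeros(n)
    v_abs = np.zeros(n)
    v_vt = np.zeros(n)
    v_lg = np.zeros(n)
    v_lt = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    valid[0] = False

    for i, hand in enumerate(hand_frames):
        cf = measure_contact(hand, arm, count=count, disc_constant=disc_constant)
        flags[i] = cf.in_contact
        area[i] = cf.area
        depth[i] = cf.depth
        if i > 0:
            dt = ts[i] - ts[i - 1]
            v_abs[i], v_vt[i], v_lg[i], v_lt[i] = decompose_velocity(
                hand.joint_position, hand_frames[i - 1].joint_position, dt, frame
            )

    return ContactAttributeSeries(
        timestamps=ts,
        contact_flags=flags,
        v_abs=v_abs,
        v_vt=v_vt,
        v_lg=v_lg,
        v_lt=v_lt,
        area=area,
        depth=depth,
        sampling_rate=f,
        velocity_valid=valid,
        metadata={"count": count, "disc_constant": disc_constant},
    )
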