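"""Core point-cloud and mesh containers.

All coordinates are metres in the camera frame. Derived quantities are
reported in the units conventional for contact attributes: indentation
depth in millimetres, contact area in square centimetres, velocities in
centimetres per second.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SurfacePointCloud",
    "ArmSurface",
    "HandMeshFrame",
    "M_TO_MM",
    "M2_TO_CM2",
    "M_TO_CM",
]

M_TO_MM = 1_000.0
M_TO_CM = 100.0
M2_TO_CM2 = 10_000.0


@dataclass
class SurfacePointCloud:
    """A surface point cloud with optional colors, normals and neighbor spacing.

    Parameters
    ----------
    points : (N, 3) float array, metres.
    colors : optional (N, 3) float array, RGB in [0, 1].
    normals : optional (N, 3) float array of unit vectors.
    neighbor_distances : optional (N,) array of per-point nearest-neighbor
        distances in metres (strictly positive).
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    normals: np.ndarray | None = None
    neighbor_distances: np.ndarray | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < 1:
            raise ValueError("point cloud must contain at least 1 point")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float)
            if self.colors.shape != self.points.shape:
                raise ValueError("colors must match points shape")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length (±1e-6)")
        if self.neighbor_distances is not None:
            self.neighbor_distances = np.asarray(self.neighbor_distances, dtype=float)
            if self.neighbor_distances.shape != (len(self.points),):
                raise ValueError("neighbor_distances must have one entry per point")
            if np.any(self.neighbor_distances <= 0):
                raise ValueError("neighbor_distances must be strictly positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        """Exact spatial index over the points (built lazily, cached)."""
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def select(self, mask_or_indices) -> "SurfacePointCloud":
        """Sub-cloud keeping per-point attributes aligned."""
        idx = np.asarray(mask_or_indices)
        return SurfacePointCloud(
            points=self.points[idx],
            colors=None if self.colors is None else self.colors[idx],
            normals=None if self.normals is None else self.normals[idx],
            neighbor_distances=None
            if self.neighbor_distances is None
            else self.neighbor_distances[idx],
        )

    def translated(self, offset) -> "SurfacePointCloud":
        """Rigidly translated copy; normals and spacing are unchanged."""
        out = dataclasses.replace(self, points=self.points + np.asarray(offset, float))
        out._tree = None
        return out


@dataclass
class ArmSurface:
    """The receiver's forearm surface, frozen at shape-extraction time.

    Holds the segmented cloud (normals oriented toward the camera, i.e. the
    outward skin side), the mean nearest-neighbor spacing that defines the
    per-point unit area, and the 3D position of the arm color marker at
    extraction time (used to keep the cloud's position current).
    """

    cloud: SurfacePointCloud
    mean_neighbor_distance: float
    marker_anchor: np.ndarray | None = None
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.cloud.normals is None:
            raise ValueError("ArmSurface requires per-point normals")
        if self.cloud.neighbor_distances is None:
            raise ValueError("ArmSurface requires per-point neighbor distances")
        expected = float(np.mean(self.cloud.neighbor_distances))
        if not np.isclose(self.mean_neighbor_distance, expected, rtol=1e-9):
            raise ValueError(
                "mean_neighbor_distance must equal the mean of cloud.neighbor_distances"
            )
        if self.marker_anchor is not None:
            self.marker_anchor = np.asarray(self.marker_anchor, dtype=float)

    @classmethod
    def from_cloud(
        cls,
        cloud: SurfacePointCloud,
        *,
        k: int = 30,
        viewpoint=(0.0, 0.0, 0.0),
        marker_anchor=None,
    ) -> "ArmSurface":
        """Build an arm surface, estimating normals/spacing if missing."""
        from .contact import estimate_normals, mean_neighbor_distance

        if cloud.normals is None:
            cloud = estimate_normals(cloud, k=k, viewpoint=viewpoint)
        if cloud.neighbor_distances is None:
            dists, _ = mean_neighbor_distance(cloud)
            cloud = dataclasses.replace(cloud, neighbor_distances=dists)
        return cls(
            cloud=cloud,
            mean_neighbor_distance=float(np.mean(cloud.neighbor_distances)),
            marker_anchor=marker_anchor,
        )

    def translated(self, offset) -> "ArmSurface":
        offset = np.asarray(offset, dtype=float)
        return ArmSurface(
            cloud=self.cloud.translated(offset),
            mean_neighbor_distance=self.mean_neighbor_distance,
            marker_anchor=None
            if self.marker_anchor is None
            else self.marker_anchor + offset,
            frozen=self.frozen,
        )


@dataclass
class HandMeshFrame:
    """One frame of the toucher's posed hand mesh.

    ``joint_position`` is the tracked reference joint — the middle
    metacarpophalangeal joint when a full hand model is available, or the
    hand marker otherwise (recorded in series metadata by the caller).
    """

    vertices: np.ndarray
    joint_position: np.ndarray
    timestamp: float
    faces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if len(self.vertices) < 1:
            raise ValueError("hand mesh must contain at least 1 vertex")
        self.joint_position = np.asarray(self.joint_position, dtype=float)
        if self.joint_position.shape != (3,):
            raise ValueError("joint_position must be a 3-vector")
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=int)
            if self.faces.size and (
                self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
            ):
                raise ValueError("face indices out of range")
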