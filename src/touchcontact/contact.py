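"""Point-based hand-to-forearm contact detection and measurement.

Contact is decided per hand vertex against the nearest arm point: with
``n`` the arm point's outward normal, a hand vertex ``p_hand`` whose
nearest arm point is ``p_arm`` lies underneath the skin surface when

    (p_hand - p_arm) . n <= 0

and the frame is in contact when at least one vertex is underneath.
Indentation depth is half the mean vertex-to-arm distance over contacted
vertices (half because the connecting segment need not be perpendicular to
the surface), and contact area assigns each contacted arm point a disc of
radius equal to the cloud's mean nearest-neighbor spacing, with the disc
constant rounded to 3.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import M2_TO_CM2, M_TO_MM, ArmSurface, HandMeshFrame, SurfacePointCloud

__all__ = [
    "ContactFrame",
    "estimate_normals",
    "mean_neighbor_distance",
    "detect_contact",
    "indentation_depth",
    "contact_area",
    "measure_contact",
]


@dataclass
class ContactFrame:
    """Per-frame contact state.

    ``arm_contact_indices`` are the distinct nearest arm points of the
    contacted hand vertices. ``depth`` is in millimetres, ``area`` in
    square centimetres; both are 0 when there is no contact. The full
    per-vertex nearest-neighbor assignment is cached so depth/area can be
    computed without re-querying.
    """

    in_contact: bool
    hand_contact_indices: np.ndarray
    arm_contact_indices: np.ndarray
    depth: float = 0.0
    area: float = 0.0
    nearest_arm_indices: np.ndarray | None = None
    nearest_arm_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hand_contact_indices = np.asarray(self.hand_contact_indices, dtype=int)
        self.arm_contact_indices = np.asarray(self.arm_contact_indices, dtype=int)
        if self.in_contact != (len(self.hand_contact_indices) > 0):
            raise ValueError("in_contact must mirror a non-empty contacted vertex set")
        if self.depth < 0 or self.area < 0:
            raise ValueError("depth and area must be non-negative")
        if not self.in_contact and (self.depth != 0 or self.area != 0):
            raise ValueError("no-contact frames must report depth = area = 0")

    @property
    def n_hand_contacts(self) -> int:
        return len(self.hand_contact_indices)

    @property
    def n_arm_contacts(self) -> int:
        return len(self.arm_contact_indices)


def estimate_normals(
    cloud: SurfacePointCloud,
    k: int = 30,
    viewpoint=(0.0, 0.0, 0.0),
) -> SurfacePointCloud:
    """Per-point unit normals from local plane fits over k nearest neighbors.

    Each normal is the smallest-variance principal direction of the point's
    k-neighborhood, flipped to point toward ``viewpoint`` (the camera side,
    i.e. the outward skin side).

    Raises
    ------
    ValueError
        If the cloud has fewer than ``k + 1`` points or ``k < 3``.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    n = len(cloud)
    if n < k + 1:
        raise ValueError(
            f"normal estimation with k={k} requires at least {k + 1} points, got {n}"
        )
    viewpoint = np.asarray(viewpoint, dtype=float)
    pts = cloud.points
    _, nbr_idx = cloud.tree.query(pts, k=k + 1)
    # neighborhoods include the point itself (first column)
    nbrs = pts[nbr_idx]  # (n, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    # collinear neighborhoods: two vanishing eigenvalues, normal direction
    # ill-defined; keep the best-fit direction but warn.
    degenerate = eigvals[:, 1] < 1e-12 * np.maximum(eigvals[:, 2], 1e-300)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} degenerate (collinear) neighborhoods; "
            "normals there are best-fit directions only",
            RuntimeWarning,
            stacklevel=2,
        )
    flip = np.einsum("ni,ni->n", viewpoint[None, :] - pts, normals) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    out = dataclasses.replace(cloud, normals=normals)
    out._tree = cloud._tree
    return out


def mean_neighbor_distance(cloud: SurfacePointCloud) -> tuple[np.ndarray, float]:
    """Distance of every point to its single nearest other point, and the mean.

    The mean spacing sets the per-point unit area used by the contact-area
    measure.
    """
    if len(cloud) < 2:
        raise ValueError("mean neighbor distance requires at least 2 points")
    dists, _ = cloud.tree.query(cloud.points, k=2)
    nn = dists[:, 1]
    return nn, float(nn.mean())


def detect_contact(hand: HandMeshFrame, arm: ArmSurface) -> ContactFrame:
    """Flag the frame and collect contacted hand-vertex / arm-point index sets.

    A hand vertex is contacted iff the vector from its nearest arm point to
    the vertex has a non-positive dot product with that arm point's outward
    normal (the boundary case, vertex exactly on the surface, counts as
    contact). The frame flag is existential: any contacted vertex suffices.
    """
    if len(hand.vertices) == 0 or len(arm.cloud) == 0:
        raise ValueError("hand mesh and arm cloud must be non-empty")
    dists, idx = arm.cloud.tree.query(hand.vertices)
    rel = hand.vertices - arm.cloud.points[idx]
    dots = np.einsum("ni,ni->n", rel, arm.cloud.normals[idx])
    contacted = np.flatnonzero(dots <= 0.0)
    arm_contacted = np.unique(idx[contacted])
    return ContactFrame(
        in_contact=len(contacted) > 0,
        hand_contact_indices=contacted,
        arm_contact_indices=arm_contacted,
        nearest_arm_indices=idx,
        nearest_arm_distances=dists,
    )


def indentation_depth(
    contact: ContactFrame, hand: HandMeshFrame, arm: ArmSurface
) -> float:
    """Mean half-distance from contacted hand vertices to their arm points, mm.

    Returns 0 for no-contact frames.
    """
    if not contact.in_contact:
        return 0.0
    if contact.nearest_arm_distances is not None:
        d = contact.nearest_arm_distances[contact.hand_contact_indices]
    else:
        d, _ = arm.cloud.tree.query(hand.vertices[contact.hand_contact_indices])
    return float(d.mean() / 2.0 * M_TO_MM)


def contact_area(
    contact: ContactFrame,
    arm: ArmSurface,
    *,
    count: str = "arm",
    disc_constant: float = 3.0,
) -> float:
    """Summed unit area of contacted arm points, cm².

    Each contacted point contributes a disc of radius equal to the arm
    cloud's mean nearest-neighbor spacing; the disc constant is 3 (pi
    rounded down, the convention this measure was defined with) and is
    configurable. ``count`` selects whether distinct contacted arm points
    (default) or contacted hand vertices are counted.
    """
    if count == "arm":
        n_c = contact.n_arm_contacts
    elif count == "hand":
        n_c = contact.n_hand_contacts
    else:
        raise ValueError("count must be 'arm' or 'hand'")
    area_m2 = disc_constant * n_c * arm.mean_neighbor_distance**2
    return float(area_m2 * M2_TO_CM2)


def measure_contact(
    hand: HandMeshFrame,
    arm: ArmSurface,
    *,
    count: str = "arm",
    disc_constant: float = 3.0,
) -> ContactFrame:
    """Detect contact and fill in depth (mm) and area (cm²) in one call."""
    frame = detect_contact(hand, arm)
    if frame.in_contact:
        frame.depth = indentation_depth(frame, hand, arm)
        frame.area = contact_area(frame, arm, count=count, disc_constant=disc_constant)
    return frame
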