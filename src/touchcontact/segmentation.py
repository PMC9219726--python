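"""Forearm extraction from colored scene clouds.

The pipeline mirrors how a depth-camera scene is reduced to a clean
forearm surface: crop and voxel-downsample, remove the background (either
the supporting table plane, found by robust consensus fitting, or a
monochromatic holder removed by HSV color thresholding), then cluster the
remainder by region growing on normal smoothness and keep the arm
cluster. During contact episodes the arm shape is frozen and only its
position is refreshed by tracking a color marker on the arm.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import rgb_to_hsv

from .cloud import ArmSurface, SurfacePointCloud
from .contact import estimate_normals

__all__ = [
    "SegmentationConfig",
    "crop_and_downsample",
    "remove_background",
    "region_growing_cluster",
    "locate_marker_and_refresh",
    "extract_arm",
]


@dataclass
class SegmentationConfig:
    """Tunable parameters for forearm extraction.

    HSV bounds are (h, s, v) triples in [0, 1]; ``hsv_range`` marks the
    background holder's color, ``marker_hsv_range`` the arm marker.
    Defaults must be tuned per scene — the lighting-dependent color
    thresholds in particular.
    """

    crop_box: tuple = ((-1.0, -1.0, -1.0), (1.0, 1.0, 1.0))
    voxel_size: float = 0.003
    background_mode: str = "plane"
    plane_distance_threshold: float = 0.005
    ransac_iterations: int = 1000
    hsv_range: tuple = ((0.20, 0.25, 0.15), (0.45, 1.0, 1.0))
    marker_hsv_range: tuple = ((0.55, 0.40, 0.15), (0.70, 1.0, 1.0))
    smoothness_threshold: float = 25.0
    min_cluster_size: int = 50
    knn: int = 30
    neighbor_distance_factor: float = 3.0
    normals_k: int = 30
    viewpoint: tuple = (0.0, 0.0, 1.0)
    cluster_selection: str = "largest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.plane_distance_threshold <= 0:
            raise ValueError("plane_distance_threshold must be positive")
        if self.smoothness_threshold <= 0:
            raise ValueError("smoothness_threshold must be positive")
        for lo, hi in (self.hsv_range, self.marker_hsv_range):
            if any(a > b for a, b in zip(lo, hi)):
                raise ValueError("HSV bounds must be ordered low <= high")


def _hsv(colors: np.ndarray) -> np.ndarray:
    return rgb_to_hsv(np.clip(colors, 0.0, 1.0))


def _hsv_mask(colors: np.ndarray, hsv_range) -> np.ndarray:
    lo, hi = (np.asarray(b, dtype=float) for b in hsv_range)
    hsv = _hsv(colors)
    return np.all((hsv >= lo) & (hsv <= hi), axis=1)


def crop_and_downsample(
    cloud: SurfacePointCloud, config: SegmentationConfig
) -> SurfacePointCloud:
    """Crop to the region of interest and keep one point per voxel.

    The survivor in each voxel is the point closest to the voxel centre,
    so original coordinates are preserved and the operation is idempotent.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in config.crop_box)
    if np.any(hi <= lo):
        raise ValueError("crop box must be non-degenerate")
    inside = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if not inside.any():
        raise ValueError("no points in region of interest")
    cropped = cloud.select(inside)

    s = config.voxel_size
    vox = np.floor(cropped.points / s).astype(np.int64)
    centres = (vox + 0.5) * s
    d2 = np.einsum("ni,ni->n", cropped.points - centres, cropped.points - centres)
    _, inverse = np.unique(vox, axis=0, return_inverse=True)
    order = np.lexsort((d2, inverse))
    keep_sorted = np.ones(len(order), dtype=bool)
    keep_sorted[1:] = inverse[order][1:] != inverse[order][:-1]
    keep = np.sort(order[keep_sorted])
    return cropped.select(keep)


def _fit_plane_ransac(points: np.ndarray, threshold: float, iterations: int, rng):
    """Largest-consensus plane by random 3-point sampling. Returns (n, d, inliers)."""
    best_inliers = None
    best_count = -1
    n_pts = len(points)
    for _ in range(iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        p0, p1, p2 = points[idx]
        normal = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(normal)
        if norm < 1e-12:
            continue
        normal = normal / norm
        dist = np.abs((points - p0) @ normal)
        inliers = dist <= threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
            best = (normal, float(normal @ p0))
    return best[0], best[1], best_inliers


def remove_background(
    cloud: SurfacePointCloud, config: SegmentationConfig
) -> SurfacePointCloud:
    """Remove the supporting surface under the forearm.

    Plane mode removes the inliers of the largest-consensus plane; if that
    plane supports fewer than 10% of the points the scene is assumed to
    have no table and is returned unchanged with a warning. Color mode
    removes points whose HSV color falls in ``hsv_range``.
    """
    if config.background_mode == "plane":
        rng = np.random.default_rng(config.seed)
        _, _, inliers = _fit_plane_ransac(
            cloud.points, config.plane_distance_threshold, config.ransac_iterations, rng
        )
        if inliers is None or inliers.sum() < 0.10 * len(cloud):
            warnings.warn(
                "no dominant plane found (support < 10%); returning cloud unchanged",
                RuntimeWarning,
                stacklevel=2,
            )
            return cloud
        return cloud.select(~inliers)
    elif config.background_mode == "color":
        if cloud.colors is None:
            raise ValueError("color background removal requires per-point colors")
        mask = _hsv_mask(cloud.colors, config.hsv_range)
        return cloud.select(~mask)
    raise ValueError(f"unknown background_mode {config.background_mode!r}")


def region_growing_cluster(
    cloud: SurfacePointCloud, config: SegmentationConfig
) -> list[np.ndarray]:
    """Cluster by growing seeds across smooth, nearby neighbors.

    A point joins its neighbor's cluster when they are within the distance
    bound (``neighbor_distance_factor`` times the cloud's mean nearest-
    neighbor spacing) and their normals deviate by less than the
    smoothness threshold. Clusters below ``min_cluster_size`` are
    discarded; the rest are returned largest-first.
    """
    if cloud.normals is None:
        raise ValueError("region growing requires estimated normals")
    n = len(cloud)
    k = min(config.knn + 1, n)
    dists, nbrs = cloud.tree.query(cloud.points, k=k)
    if n > 1:
        bound = config.neighbor_distance_factor * float(dists[:, 1].mean())
    else:
        bound = np.inf
    cos_thresh = np.cos(np.deg2rad(config.smoothness_threshold))
    normals = cloud.normals

    labels = np.full(n, -1, dtype=int)
    current = 0
    for seed in range(n):
        if labels[seed] >= 0:
            continue
        labels[seed] = current
        stack = [seed]
        while stack:
            i = stack.pop()
            for j, dij in zip(nbrs[i, 1:], dists[i, 1:]):
                if labels[j] >= 0 or dij > bound:
                    continue
                if abs(normals[i] @ normals[j]) >= cos_thresh:
                    labels[j] = current
                    stack.append(j)
        current += 1

    clusters = [np.flatnonzero(labels == c) for c in range(current)]
    clusters = [c for c in clusters if len(c) >= config.min_cluster_size]
    clusters.sort(key=len, reverse=True)
    return clusters


def locate_marker(scene: SurfacePointCloud, config: SegmentationConfig) -> np.ndarray:
    """3D centroid of the scene points inside the marker's HSV range."""
    if scene.colors is None:
        raise ValueError("marker detection requires per-point colors")
    mask = _hsv_mask(scene.colors, config.marker_hsv_range)
    if not mask.any():
        raise ValueError("marker not found: no scene points in the marker HSV range")
    return scene.points[mask].mean(axis=0)


def locate_marker_and_refresh(
    scene: SurfacePointCloud, arm: ArmSurface, config: SegmentationConfig
) -> ArmSurface:
    """Rigidly translate the frozen arm cloud to follow the color marker.

    The arm shape is never updated during contact (the contacted region is
    occluded); only its position tracks the marker.
    """
    if arm.marker_anchor is None:
        raise ValueError("arm surface has no marker anchor from extraction time")
    marker_now = locate_marker(scene, config)
    refreshed = arm.translated(marker_now - arm.marker_anchor)
    refreshed.frozen = True
    return refreshed


def extract_arm(
    scene: SurfacePointCloud, config: SegmentationConfig
) -> ArmSurface:
    """Full pre-contact pipeline: crop, downsample, background removal,
    region growing, arm-cluster selection, normals and marker anchor."""
    cloud = crop_and_downsample(scene, config)
    cloud = remove_background(cloud, config)
    cloud = estimate_normals(cloud, k=min(config.normals_k, len(cloud) - 1),
                             viewpoint=config.viewpoint)
    clusters = region_growing_cluster(cloud, config)
    if not clusters:
        raise ValueError("no cluster above min_cluster_size; cannot extract arm")
    if config.cluster_selection == "largest":
        chosen = clusters[0]
    elif config.cluster_selection == "marker":
        marker = locate_marker(cloud, config)
        dmin = [np.linalg.norm(cloud.points[c] - marker, axis=1).min() for c in clusters]
        chosen = clusters[int(np.argmin(dmin))]
    else:
        raise ValueError("cluster_selection must be 'largest' or 'marker'")
    arm_cloud = cloud.select(chosen)
    arm_cloud = dataclasses.replace(arm_cloud, neighbor_distances=None)
    anchor = None
    if arm_cloud.colors is not None:
        try:
            anchor = locate_marker(arm_cloud, config)
        except ValueError:
            anchor = None
    return ArmSurface.from_cloud(arm_cloud, marker_anchor=anchor)
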