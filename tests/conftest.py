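import numpy as np
import pytest

import touchcontact as tc


@pytest.fixture(scope="session")
def default_arm():
    """One shared synthetic forearm (R = 4 cm, L = 25 cm, 2 mm grid)."""
    return tc.make_forearm()


@pytest.fixture(scope="session")
def arm_frame():
    """Arm triad for the canonical camera pose (z up, y longitudinal)."""
    return tc.build_arm_frame((0.0, 0.0, 1.0), (0.0, 1.0, 0.0))


def brute_force_nearest(query, points):
    """Exhaustive O(N*M) nearest-neighbor oracle."""
    query = np.asarray(query, float)
    points = np.asarray(points, float)
    diff = query[:, None, :] - points[None, :, :]
    d2 = np.einsum("nmi,nmi->nm", diff, diff)
    idx = np.argmin(d2, axis=1)
    return np.sqrt(d2[np.arange(len(query)), idx]), idx


def scattered_plane(pitch, half_extent, rng, jitter_sd_frac=0.4):
    """Plane cloud sampled at a given pitch with sensor-like lateral scatter."""
    n = int(round(2 * half_extent / pitch))
    gx, gy = np.meshgrid(
        (np.arange(n) - n / 2 + 0.5) * pitch,
        (np.arange(n) - n / 2 + 0.5) * pitch,
        indexing="ij",
    )
    pts = np.column_stack(
        [
            (gx + rng.normal(0, jitter_sd_frac * pitch, gx.shape)).ravel(),
            (gy + rng.normal(0, jitter_sd_frac * pitch, gy.shape)).ravel(),
            np.zeros(n * n),
        ]
    )
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    cloud = tc.SurfacePointCloud(points=pts, normals=normals)
    return tc.ArmSurface.from_cloud(cloud)


def fibonacci_sphere(n, radius):
    """Near-uniform sphere sampling (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z * z)
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sphere_hand(radius, centre_z, spacing=0.0004, timestamp=0.0):
    """Rigid sphere mesh frame centred on the z-axis."""
    n = int(4 * np.pi * radius**2 / spacing**2)
    verts = fibonacci_sphere(n, radius) + np.array([0.0, 0.0, centre_z])
    return tc.HandMeshFrame(
        vertices=verts, joint_position=[0.0, 0.0, centre_z], timestamp=timestamp
    )
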