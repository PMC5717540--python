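"""Geometric ROI preprocessing: surface plane fit, rotation, crop, regrid.

A reconstructed conductivity field lives on an irregular point set (FEM mesh
solution values). To analyse it laminarly the cortical patch under the
electrode array is rotated so the fitted surface normal points along +z, the
field is cropped at a maximum cortical depth, and resampled onto a regular
lattice by piecewise-linear (Delaunay barycentric) interpolation.

Depth convention: after rotation the surface is the plane of maximum z, and
``depth = max(surface z) - z`` increases from the pial surface downward. The
fitted normal's sign is chosen to point from tissue toward the array (+z after
rotation) so that depths are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .grid import VoxelGrid

__all__ = [
    "SurfaceMesh",
    "PointCloudField",
    "PlaneFit",
    "triangle_centroids",
    "fit_plane",
    "rotation_to_z",
    "rotate_points",
    "depth_crop",
    "interpolate_to_grid",
]


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (µm) and triangle vertex-index triples."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of vertex range")

    def degenerate_triangles(self) -> np.ndarray:
        """Boolean flag per triangle: True where the triangle has zero area."""
        v = self.vertices[self.triangles]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return np.linalg.norm(cross, axis=1) == 0.0


@dataclass
class PointCloudField:
    """Scalar values sampled at scattered 3D positions (µm)."""

    points: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.points) != len(self.values):
            raise ValueError("points and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class PlaneFit:
    """Least-squares plane z = a x + b y + c with its unit normal.

    The unit normal is proportional to (-a, -b, 1), oriented toward +z.
    """

    coefficients: tuple[float, float, float]
    unit_normal: np.ndarray

    def __post_init__(self) -> None:
        self.unit_normal = np.asarray(self.unit_normal, dtype=float)
        if abs(np.linalg.norm(self.unit_normal) - 1.0) > 1e-9:
            raise ValueError("unit_normal must have unit length")


def triangle_centroids(mesh: SurfaceMesh) -> np.ndarray:
    """Per-triangle centroid: arithmetic mean of its three vertex positions."""
    if len(mesh.triangles) == 0:
        raise ValueError("mesh has no triangles")
    return mesh.vertices[mesh.triangles].mean(axis=1)


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Ordinary least squares fit of z = a x + b y + c to scattered points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError(f"plane fit needs at least 3 points, got {len(pts)}")
    design = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("points are collinear (or otherwise rank-deficient); plane fit is underdetermined")
    coef, *_ = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    a, b, c = (float(v) for v in coef)
    normal = np.array([-a, -b, 1.0])
    normal /= np.linalg.norm(normal)
    return PlaneFit((a, b, c), normal)


def rotation_to_z(unit_normal: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``unit_normal`` to +z (Rodrigues construction).

    Rotates about the axis ``normal × ẑ`` by ``arccos(normal · ẑ)``; the
    antiparallel case (normal = -z) uses a half-turn about x.
    """
    n = np.asarray(unit_normal, dtype=float).ravel()
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("cannot align a zero vector with the z axis")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"expected a unit vector, got length {norm}")
    n = n / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(n, z), -1.0, 1.0))
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about the x axis
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def rotate_points(points: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Apply a rotation matrix to each point (values are never transformed)."""
    pts = np.asarray(points, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    return pts @ rotation.T


def depth_crop(field: PointCloudField, max_depth_um: float) -> PointCloudField:
    """Discard points deeper than ``max_depth_um`` below the surface.

    Assumes points are already rotated; the surface is the maximum z of the
    cloud and depth increases downward (depth = max z - z).
    """
    z = field.points[:, 2]
    depth = z.max() - z
    keep = depth <= max_depth_um
    return PointCloudField(field.points[keep], field.values[keep])


def interpolate_to_grid(field: PointCloudField, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear resampling of a scattered field onto a regular lattice.

    Returns ``(volume, valid)``: lattice points outside the convex hull of the
    point cloud are not extrapolated; they are NaN in ``volume`` and False in
    ``valid``.
    """
    if len(field.points) < 4:
        raise ValueError("interpolation needs at least 4 non-coplanar points")
    try:
        interp = LinearNDInterpolator(field.points, field.values)
    except QhullError as err:
        raise ValueError("points are coplanar; 3D linear interpolation is undefined") from err
    x, y, z = grid.coordinate_arrays()
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    vol = interp(np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])).reshape(grid.dims)
    valid = np.isfinite(vol)
    return vol, valid
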