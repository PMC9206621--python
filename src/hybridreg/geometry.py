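"""Rigid-body poses, the perspective camera model and the bone volume container.

Conventions used throughout the package:

* All lengths are millimetres, all angles degrees.
* The camera frame has the X-ray point source at the origin and the
  detector plane at ``z = source_to_detector_distance``; ``x`` runs along
  detector columns, ``y`` along detector rows.
* A bone volume lives in its own object frame, centred on the voxel grid
  centre; at the reference (identity) pose that centre sits on the optical
  axis at ``z = source_to_object_distance``.
* A :class:`RigidPose` rotates the volume about its grid centre with fixed
  axes in the order Rx, then Ry, then Rz, and then translates it.  The
  in-plane parameters are (tx, ty, rz) — parallel to the detector — and the
  out-of-plane ones (tz, rx, ry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Raised for physically impossible camera/volume configurations."""


class GimbalLockWarning(UserWarning):
    """Euler-angle extraction near ``|ry| = 90°`` is not unique."""


@dataclass(frozen=True)
class RigidPose:
    """Six-parameter rigid transform: translations in mm, rotations in degrees."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], dtype=float)

    @classmethod
    def from_array(cls, a) -> "RigidPose":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())

    def replace(self, **kw) -> "RigidPose":
        return replace(self, **kw)

    @property
    def inplane(self):
        return (self.tx, self.ty, self.rz)

    def matrix(self) -> np.ndarray:
        return pose_to_matrix(self)

    def inverse(self) -> "RigidPose":
        return matrix_to_pose(np.linalg.inv(pose_to_matrix(self)))


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """3x3 rotation for fixed-axes rotations applied in the order x, y, z."""
    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()


def pose_to_matrix(pose: RigidPose) -> np.ndarray:
    """4x4 homogeneous matrix of a pose (rotation about the object origin)."""
    m = np.eye(4)
    m[:3, :3] = rotation_matrix(pose.rx, pose.ry, pose.rz)
    m[:3, 3] = [pose.tx, pose.ty, pose.tz]
    return m


def matrix_to_pose(matrix: np.ndarray) -> RigidPose:
    """Extract the six pose parameters from a 4x4 rigid transform.

    Warns with :class:`GimbalLockWarning` when ``|ry|`` is within ~0.01° of
    90°, where the x/z split is no longer unique (a valid decomposition is
    still returned).
    """
    matrix = np.asarray(matrix, dtype=float)
    r = matrix[:3, :3]
    if abs(abs(r[2, 0]) - 1.0) < 3e-7:
        warnings.warn("|ry| ~ 90 deg: Euler decomposition not unique", GimbalLockWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy's own gimbal-lock warning
        rx, ry, rz = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
    tx, ty, tz = matrix[:3, 3]
    return RigidPose(tx, ty, tz, rx, ry, rz)


def compose(a: RigidPose, b: RigidPose) -> RigidPose:
    """Pose whose matrix is ``matrix(a) @ matrix(b)``."""
    return matrix_to_pose(pose_to_matrix(a) @ pose_to_matrix(b))


def transform_points(pose: RigidPose, points) -> np.ndarray:
    """Apply a pose to an ``(..., 3)`` array of object-frame points."""
    points = np.asarray(points, dtype=float)
    r = rotation_matrix(pose.rx, pose.ry, pose.rz)
    return points @ r.T + np.array([pose.tx, pose.ty, pose.tz])


@dataclass(frozen=True)
class CameraModel:
    """Point-source/flat-detector geometry of an image intensifier.

    ``magnification`` is the ratio by which structures in the object plane
    (the plane through the volume centre, normal to the optical axis) are
    enlarged on the detector.
    """

    source_to_detector_distance: float
    source_to_object_distance: float
    detector_pixel_pitch: float
    detector_size: tuple = (160, 160)  # (rows, cols)
    principal_point: tuple | None = None  # (row, col), defaults to centre

    def __post_init__(self):
        if self.source_to_detector_distance <= 0 or self.source_to_object_distance <= 0:
            raise GeometryError("source distances must be strictly positive")
        if self.detector_pixel_pitch <= 0:
            raise GeometryError("detector pixel pitch must be strictly positive")
        if self.source_to_object_distance >= self.source_to_detector_distance:
            raise GeometryError("object must lie between source and detector")
        if self.principal_point is None:
            rows, cols = self.detector_size
            object.__setattr__(self, "principal_point", ((rows - 1) / 2.0, (cols - 1) / 2.0))

    @property
    def magnification(self) -> float:
        return self.source_to_detector_distance / self.source_to_object_distance

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            source_to_detector_distance=float(d["source_to_detector_distance"]),
            source_to_object_distance=float(d["source_to_object_distance"]),
            detector_pixel_pitch=float(d["detector_pixel_pitch"]),
            detector_size=tuple(d.get("detector_size", (160, 160))),
            principal_point=tuple(d["principal_point"]) if "principal_point" in d else None,
        )

    def to_dict(self) -> dict:
        return {
            "source_to_detector_distance": self.source_to_detector_distance,
            "source_to_object_distance": self.source_to_object_distance,
            "detector_pixel_pitch": self.detector_pixel_pitch,
            "detector_size": list(self.detector_size),
            "principal_point": list(self.principal_point),
        }


def project_point(camera: CameraModel, point_mm) -> np.ndarray:
    """Pinhole projection of camera-frame points onto the detector.

    Parameters
    ----------
    point_mm : array-like, shape (..., 3)
        Points in the camera frame (source at origin, optical axis +z).

    Returns
    -------
    ndarray, shape (..., 2)
        Detector pixel coordinates ``(row, col)``.
    """
    p = np.asarray(point_mm, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise GeometryError("point at or behind the X-ray source cannot be projected")
    sdd = camera.source_to_detector_distance
    pitch = camera.detector_pixel_pitch
    ppr, ppc = camera.principal_point
    col = ppc + (p[..., 0] * sdd / z) / pitch
    row = ppr + (p[..., 1] * sdd / z) / pitch
    return np.stack([row, col], axis=-1)


@dataclass(frozen=True)
class Volume3D:
    """Segmented bone attenuation grid with physical spacing.

    ``voxels`` is indexed ``[ix, iy, iz]`` along the object-frame x, y, z
    axes.  ``origin`` is the mm position of voxel ``(0, 0, 0)`` in the object
    frame; the default centres the grid on the origin so rotations act about
    the volume centre.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple | None = None

    def __post_init__(self):
        vox = np.ascontiguousarray(np.asarray(self.voxels, dtype=np.float64))
        object.__setattr__(self, "voxels", vox)
        spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in spacing):
            raise GeometryError("voxel spacing must be strictly positive on all axes")
        object.__setattr__(self, "spacing", spacing)
        if vox.ndim != 3:
            raise GeometryError("voxel grid must be three-dimensional")
        if np.any(vox < 0):
            raise GeometryError("attenuation values must be non-negative")
        if self.origin is None:
            origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(vox.shape, spacing))
        else:
            origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self):
        return self.voxels.shape

    def voxel_centers(self) -> tuple:
        """1-D mm coordinate arrays of voxel centres along each axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def support_box(self) -> tuple:
        """Index-space bounds (lo, hi) of nonzero voxels, padded one voxel.

        Cached after the first call; used to clip rays during projection.
        An all-zero volume returns the full grid.
        """
        cached = getattr(self, "_support_box", None)
        if cached is not None:
            return cached
        lo = np.zeros(3)
        hi = np.array([n - 1.0 for n in self.shape])
        nz = np.nonzero(self.voxels)
        if nz[0].size:
            for a in range(3):
                lo[a] = max(0.0, nz[a].min() - 1.0)
                hi[a] = min(self.shape[a] - 1.0, nz[a].max() + 1.0)
        box = (lo, hi)
        object.__setattr__(self, "_support_box", box)
        return box

    def attenuation_centroid(self) -> np.ndarray:
        """Attenuation-weighted centre of mass, object-frame mm."""
        total = self.voxels.sum()
        if total == 0:
            return np.zeros(3)
        cx, cy, cz = self.voxel_centers()
        return np.array(
            [
                (self.voxels.sum(axis=(1, 2)) * cx).sum() / total,
                (self.voxels.sum(axis=(0, 2)) * cy).sum() / total,
                (self.voxels.sum(axis=(0, 1)) * cz).sum() / total,
            ]
        )
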