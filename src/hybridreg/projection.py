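"""Digitally reconstructed radiograph (DRR) generation by ray casting.

Each detector pixel receives the line integral of attenuation along the ray
from the point source through that pixel, approximated by fixed-step
sampling with trilinear interpolation.  Samples outside the volume
contribute zero, so pixels whose ray misses the volume are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import drr_cast
from .geometry import CameraModel, GeometryError, RigidPose, Volume3D, rotation_matrix


@dataclass(frozen=True)
class Image2D:
    """A 2-D scalar image (fluoroscopy frame or DRR) with pixel pitch in mm."""

    pixels: np.ndarray
    pitch: float = 1.0

    def __post_init__(self):
        px = np.ascontiguousarray(np.asarray(self.pixels, dtype=np.float64))
        if px.ndim != 2:
            raise ValueError("Image2D requires a 2-D pixel array")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must be finite")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be strictly positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


class ProjectionCounter:
    """Counts DRR projections, the unit of work for efficiency comparisons."""

    def __init__(self):
        self.count = 0

    def reset(self) -> None:
        self.count = 0


#: Module-level counter incremented by every :func:`project_drr` call.
PROJECTION_COUNTER = ProjectionCounter()


def default_step(volume: Volume3D) -> float:
    """Default ray-marching step: half the smallest voxel spacing."""
    return 0.5 * min(volume.spacing)


def project_drr(
    volume: Volume3D,
    pose: RigidPose,
    camera: CameraModel,
    step_mm: float | None = None,
    orthographic: bool = False,
) -> Image2D:
    """Cast a DRR of ``volume`` held at ``pose`` through ``camera``.

    Parameters
    ----------
    step_mm
        Ray-marching step; defaults to half the smallest voxel spacing.
    orthographic
        Parallel rays along the optical axis, 1:1 pixel scaling.  Intended
        for analytic tests only; the physical model is the perspective one.
    """
    if step_mm is None:
        step_mm = default_step(volume)
    if step_mm <= 0:
        raise ValueError("step_mm must be strictly positive")

    r = rotation_matrix(pose.rx, pose.ry, pose.rz)
    tfull = np.array(
        [pose.tx, pose.ty, camera.source_to_object_distance + pose.tz], dtype=float
    )
    if not orthographic:
        # reject geometry with the source inside the volume's bounding sphere
        half_diag = 0.5 * np.linalg.norm(
            [(n - 1) * s for n, s in zip(volume.shape, volume.spacing)]
        )
        if np.linalg.norm(tfull) <= half_diag:
            raise GeometryError("X-ray source lies inside the volume bounding box")

    rows, cols = camera.detector_size
    ppr, ppc = camera.principal_point
    lo, hi = volume.support_box()
    pixels = drr_cast(
        volume.voxels,
        np.asarray(volume.origin, dtype=float),
        np.asarray(volume.spacing, dtype=float),
        np.ascontiguousarray(r.T),
        tfull,
        camera.source_to_detector_distance,
        camera.detector_pixel_pitch,
        float(ppr),
        float(ppc),
        int(rows),
        int(cols),
        float(step_mm),
        1 if orthographic else 0,
        lo,
        hi,
    )
    PROJECTION_COUNTER.count += 1
    return Image2D(pixels, camera.detector_pixel_pitch)


def drr_is_linear(
    volume_a: Volume3D,
    volume_b: Volume3D,
    pose: RigidPose,
    camera: CameraModel,
    step_mm: float | None = None,
    tol: float = 1e-6,
) -> bool:
    """Check additivity of the projection operator on two volumes.

    Returns True when ``DRR(A + B) == DRR(A) + DRR(B)`` within ``tol`` of the
    combined dynamic range — a direct consequence of the line-integral model.
    """
    if volume_a.shape != volume_b.shape or volume_a.spacing != volume_b.spacing:
        raise ValueError("volumes must share shape and spacing")
    combined = Volume3D(
        volume_a.voxels + volume_b.voxels, volume_a.spacing, volume_a.origin
    )
    pa = project_drr(volume_a, pose, camera, step_mm).pixels
    pb = project_drr(volume_b, pose, camera, step_mm).pixels
    pab = project_drr(combined, pose, camera, step_mm).pixels
    scale = max(pab.max(), (pa + pb).max(), 1e-300)
    return bool(np.max(np.abs(pab - (pa + pb))) <= tol * scale)
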