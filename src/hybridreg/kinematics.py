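"""Knee joint kinematics from registered femur and tibia poses.

The six relational parameters follow the floating-axis joint coordinate
system (Grood-Suntay convention): flexion-extension about the femoral
medial-lateral axis e1, internal-external rotation about the tibial long
axis e3, and abduction-adduction about the mutually perpendicular floating
axis e2 = e3 x e1.  Translations are the components of the femoral-origin
to tibial-origin vector in the (generally non-orthogonal) joint axis basis:
medial-lateral shift along e1, anterior-posterior draw along e2 and
distraction-compression along e3.

All parameters are reported relative to the reference (CT capture)
configuration: when neither bone has moved, every parameter is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import RigidPose, pose_to_matrix


class DegenerateConfigurationError(ValueError):
    """Femoral e1 and tibial e3 near-parallel: the floating axis is undefined."""


@dataclass(frozen=True)
class BoneAxes:
    """Anatomical frame of one bone in its own CT/object frame.

    ``axes`` holds unit direction columns: medial-lateral, anterior-
    posterior and proximal-distal.  Must be orthonormal and right-handed.
    """

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = (ml, ap, pd)

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-9):
            raise ValueError("anatomical axes must be orthonormal within 1e-9")
        if np.linalg.det(axes) < 0:
            raise ValueError("anatomical axes must form a right-handed frame")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @classmethod
    def canonical(cls, origin=(0.0, 0.0, 0.0)) -> "BoneAxes":
        """Axes of the synthetic phantoms: ml = x, ap = z, pd (long) = y.

        The phantom bones are constructed with the shaft along the object
        y axis and the detector in the x-y plane, so the anterior-posterior
        direction is the optical axis z.
        """
        # (ml, ap, pd) = (x, -z, y); ap points from detector toward source,
        # which keeps the frame right-handed
        axes = np.column_stack([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        return cls(np.asarray(origin, dtype=float), axes)


@dataclass(frozen=True)
class AnatomicalAxes:
    femur: BoneAxes
    tibia: BoneAxes


def _wrap_angle(a: float) -> float:
    """Wrap degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class KinematicParams:
    """The six relational knee parameters: angles in degrees, shifts in mm."""

    flexion_extension: float = 0.0
    abduction_adduction: float = 0.0
    internal_external: float = 0.0
    medial_lateral: float = 0.0
    anterior_posterior: float = 0.0
    distraction_compression: float = 0.0

    def __post_init__(self):
        vals = [getattr(self, f.name) for f in fields(self)]
        if not np.all(np.isfinite(vals)):
            raise ValueError("kinematic parameters must be finite")
        for name in ("flexion_extension", "abduction_adduction", "internal_external"):
            object.__setattr__(self, name, _wrap_angle(getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @staticmethod
    def names() -> list:
        return [f.name for f in fields(KinematicParams)]


def relative_pose(femur_pose: RigidPose, tibia_pose: RigidPose) -> np.ndarray:
    """Tibia frame expressed in the femur frame: inv(M_femur) @ M_tibia."""
    return np.linalg.inv(pose_to_matrix(femur_pose)) @ pose_to_matrix(tibia_pose)


def _gs_raw(rel: np.ndarray, axes: AnatomicalAxes):
    """Raw floating-axis angles and joint-basis translations for one transform."""
    r = rel[:3, :3]
    t = rel[:3, 3]
    af = axes.femur.axes
    at = axes.tibia.axes
    q = af.T @ r @ at
    # intrinsic x-y'-z'' Cardan sequence == floating-axis decomposition with
    # e1 = femoral ml, e3 = tibial pd
    if abs(abs(q[0, 2]) - 1.0) < 1e-9 or abs(q[0, 2]) > 1.0 - 1e-9:
        raise DegenerateConfigurationError(
            "femoral medial-lateral and tibial long axes are near-parallel"
        )
    ang = Rotation.from_matrix(q).as_euler("XYZ", degrees=True)
    e1 = af[:, 0]
    e3 = r @ at[:, 2]
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2)
    if n2 < 1e-9:
        raise DegenerateConfigurationError("floating axis undefined")
    e2 /= n2
    basis = np.column_stack([e1, e2, e3])
    d = r @ axes.tibia.origin + t - axes.femur.origin
    trans = np.linalg.solve(basis, d)
    return ang, trans, basis


def jcs_decompose(rel: np.ndarray, axes: AnatomicalAxes) -> KinematicParams:
    """Six relational parameters of a femur-to-tibia transform.

    Offset-referenced to the reference configuration: the identity
    transform returns all zeros.
    """
    ang, trans, _ = _gs_raw(np.asarray(rel, dtype=float), axes)
    ang0, trans0, _ = _gs_raw(np.eye(4), axes)
    return KinematicParams(
        flexion_extension=ang[0] - ang0[0],
        abduction_adduction=ang[1] - ang0[1],
        internal_external=ang[2] - ang0[2],
        medial_lateral=trans[0] - trans0[0],
        anterior_posterior=trans[1] - trans0[1],
        distraction_compression=trans[2] - trans0[2],
    )


def jcs_recompose(params: KinematicParams, axes: AnatomicalAxes) -> np.ndarray:
    """Inverse of :func:`jcs_decompose`: rebuild the relative transform."""
    ang0, trans0, _ = _gs_raw(np.eye(4), axes)
    ang = np.array(
        [
            params.flexion_extension + ang0[0],
            params.abduction_adduction + ang0[1],
            params.internal_external + ang0[2],
        ]
    )
    q = Rotation.from_euler("XYZ", ang, degrees=True).as_matrix()
    af = axes.femur.axes
    at = axes.tibia.axes
    r = af @ q @ at.T
    e1 = af[:, 0]
    e3 = r @ at[:, 2]
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2)
    basis = np.column_stack([e1, e2, e3])
    trans = np.array(
        [
            params.medial_lateral + trans0[0],
            params.anterior_posterior + trans0[1],
            params.distraction_compression + trans0[2],
        ]
    )
    d = basis @ trans
    t = d - r @ axes.tibia.origin + axes.femur.origin
    rel = np.eye(4)
    rel[:3, :3] = r
    rel[:3, 3] = t
    return rel


_UNITS = {
    "flexion_extension": "deg",
    "abduction_adduction": "deg",
    "internal_external": "deg",
    "medial_lateral": "mm",
    "anterior_posterior": "mm",
    "distraction_compression": "mm",
}


def error_statistics(estimated: list, truth: list) -> pd.DataFrame:
    """Per-parameter mean error, SD of error (n-1) and mean absolute error.

    Shaped like the per-parameter accuracy tables of cadaveric validation
    studies; rotations are in degrees and translations in mm.
    """
    if len(estimated) != len(truth):
        raise ValueError("estimated and truth must have equal length")
    if len(estimated) == 0:
        raise ValueError("need at least one sample")
    est = np.array([p.as_array() for p in estimated])
    tru = np.array([p.as_array() for p in truth])
    err = est - tru
    names = KinematicParams.names()
    sd = err.std(axis=0, ddof=1) if err.shape[0] > 1 else np.zeros(err.shape[1])
    return pd.DataFrame(
        {
            "parameter": names,
            "units": [_UNITS[n] for n in names],
            "mean_error": err.mean(axis=0),
            "sd_error": sd,
            "mean_abs_error": np.abs(err).mean(axis=0),
        }
    ).set_index("parameter")
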