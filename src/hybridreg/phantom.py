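"""Synthetic bone phantoms and simulated fluoroscopy with known ground truth.

The study this package targets — recovering the six rigid-body parameters
of a knee bone from single-plane fluoroscopy — was designed around a
27-position factorial grid of out-of-plane perturbations
(Rx, Ry in {-5, 0, 5} degrees, Tz in {-20, -10, 0} mm).  This module
replaces the cadaveric CT and image-intensifier frames of such a study
with analytically constructed phantoms: a bone-like volume (cortical shell
around a lower-attenuation trabecular interior, on exactly-zero
background) and fluoroscopy frames derived from it by DRR projection, a
monotone nonlinear intensity remap, additive Gaussian noise, and optional
pincushion distortion.  Every output is a pure function of its spec,
including the seeds.

The default intensity remap (inversion followed by gamma 0.6) makes the
DRR-to-fluoroscopy relationship monotone but decidedly non-affine, so
sum-of-squared-difference style measures would fail and the multimodal
EPD/SCV measures are genuinely exercised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import CameraModel, RigidPose, Volume3D
from .preprocess import apply_distortion
from .projection import Image2D, project_drr


class PhantomSpecError(ValueError):
    """The requested bone does not fit the voxel grid."""


class FieldOfViewError(ValueError):
    """The projected bone leaves the detector."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and attenuation of a synthetic bone.

    The bone runs along the object-frame y axis (its long, proximal-distal
    axis), which at the reference pose is parallel to the detector — the
    bone appears vertical in the image.  It occupies the central 60% of
    the grid's y extent: a cylindrical
    shaft capped, for the femur-like kind, by a spherical condylar end and,
    for the tibia-like kind, by a flat plateau disc.  Attenuations are
    arbitrary linear-attenuation units; only their ratio matters.
    """

    shape: tuple = (64, 64, 64)
    spacing: float = 1.0
    kind: str = "femur"  # "femur" | "tibia"
    cortical_attenuation: float = 1.0
    trabecular_attenuation: float = 0.3
    shaft_radius: float = 7.0
    shell_thickness: float = 2.5
    condyle_radius: float = 10.0
    texture_amplitude: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if not (self.cortical_attenuation > self.trabecular_attenuation > 0):
            raise PhantomSpecError("require cortical > trabecular > 0 attenuation")
        if not (0 < self.shell_thickness < self.shaft_radius):
            raise PhantomSpecError("shell thickness must be below the shaft radius")
        if self.kind not in ("femur", "tibia"):
            raise PhantomSpecError(f"unknown bone kind: {self.kind!r}")
        half_x = (self.shape[0] - 1) * self.spacing / 2.0
        half_z = (self.shape[2] - 1) * self.spacing / 2.0
        if self.condyle_radius + self.spacing > min(half_x, half_z):
            raise PhantomSpecError("grid too small to contain the bone at this spacing")


def _sdf_capped_cylinder(x, y, z, radius, y0, y1):
    """Signed distance to a y-aligned capped cylinder (negative inside)."""
    d_r = np.hypot(x, z) - radius
    d_y = np.maximum(y0 - y, y - y1)
    inside = np.minimum(np.maximum(d_r, d_y), 0.0)
    outside = np.hypot(np.maximum(d_r, 0.0), np.maximum(d_y, 0.0))
    return inside + outside


def _sdf_sphere(x, y, z, cx, cy, cz, radius):
    return np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) - radius


def phantom_sdf(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Signed distance (mm, negative inside) of the bone surface at mm points."""
    ly = (spec.shape[1] - 1) * spec.spacing
    y_lo, y_hi = -0.3 * ly, 0.3 * ly
    if spec.kind == "femur":
        head_y = y_hi - spec.condyle_radius
        shaft = _sdf_capped_cylinder(x, y, z, spec.shaft_radius, y_lo, head_y)
        head = _sdf_sphere(x, y, z, 0.0, head_y, 0.0, spec.condyle_radius)
    else:  # tibia: flat plateau disc at the proximal end of the shaft
        plateau_h = 0.6 * spec.condyle_radius
        shaft = _sdf_capped_cylinder(x, y, z, spec.shaft_radius, y_lo, y_hi - plateau_h)
        head = _sdf_capped_cylinder(x, y, z, spec.condyle_radius, y_hi - plateau_h, y_hi)
    return np.minimum(shaft, head)


def generate_phantom(spec: PhantomSpec) -> Volume3D:
    """Voxelise a bone phantom: cortical shell + trabecular interior.

    Voxels within ``shell_thickness`` (inward) of the analytic surface get
    the cortical attenuation; deeper voxels get the trabecular attenuation
    modulated by a mild seeded texture; background is exactly zero.
    """
    nx, ny, nz = spec.shape
    s = spec.spacing
    x = (np.arange(nx) - (nx - 1) / 2.0)[:, None, None] * s
    y = (np.arange(ny) - (ny - 1) / 2.0)[None, :, None] * s
    z = (np.arange(nz) - (nz - 1) / 2.0)[None, None, :] * s
    sdf = phantom_sdf(spec, x, y, z)
    inside = sdf < 0
    cortical = inside & (sdf >= -spec.shell_thickness)
    trabecular = inside & ~cortical
    vox = np.zeros(spec.shape)
    vox[cortical] = spec.cortical_attenuation
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(spec.rng_seed)
        texture = 1.0 + spec.texture_amplitude * rng.standard_normal(spec.shape)
        np.clip(texture, 0.5, 1.5, out=texture)
        vox[trabecular] = spec.trabecular_attenuation * texture[trabecular]
    else:
        vox[trabecular] = spec.trabecular_attenuation
    return Volume3D(vox, (s, s, s))


@dataclass(frozen=True)
class FluoroSimSpec:
    """Fluoroscopy appearance model applied on top of the DRR.

    ``invert`` plus ``gamma`` define the monotone nonlinear intensity remap
    relating the two modalities; ``noise_sigma`` is the Gaussian noise SD
    as a fraction of the unit dynamic range; ``distortion_k1/k2`` are
    radial pincushion coefficients (radius normalised by the image
    half-diagonal).
    """

    invert: bool = True
    gamma: float = 0.6
    noise_sigma: float = 0.02
    distortion_k1: float = 0.0
    distortion_k2: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma exponent must be strictly positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def remap_intensities(drr: Image2D, sim: FluoroSimSpec) -> Image2D:
    """The deterministic part of the fluoroscopy model: normalise + remap."""
    peak = drr.pixels.max()
    if peak <= 0:
        raise FieldOfViewError("DRR is empty: volume projects outside the detector")
    d = drr.pixels / peak
    if sim.invert:
        d = 1.0 - d
    d = d**sim.gamma
    return Image2D(d, drr.pitch)


def simulate_fluoroscopy(
    volume: Volume3D,
    true_pose: RigidPose,
    camera: CameraModel,
    sim: FluoroSimSpec,
    step_mm: float | None = None,
) -> Image2D:
    """Simulate one fluoroscopy frame of ``volume`` held at ``true_pose``.

    Pipeline: DRR -> monotone intensity remap -> additive Gaussian noise
    (seeded) -> optional radial pincushion distortion.  The deterministic
    signal is normalised to [0, 1]; noise is left unclipped so its
    distribution is exactly the stated Gaussian.  Raises
    :class:`FieldOfViewError` when the projection leaves the detector.
    """
    drr = project_drr(volume, true_pose, camera, step_mm)
    border = np.concatenate(
        [drr.pixels[0], drr.pixels[-1], drr.pixels[:, 0], drr.pixels[:, -1]]
    )
    if np.any(border > 0):
        raise FieldOfViewError("projected bone touches the detector border")
    out = remap_intensities(drr, sim)
    pixels = out.pixels
    if sim.noise_sigma > 0:
        rng = np.random.default_rng(sim.rng_seed)
        pixels = pixels + sim.noise_sigma * rng.standard_normal(pixels.shape)
    frame = Image2D(pixels, drr.pitch)
    if sim.distortion_k1 != 0.0 or sim.distortion_k2 != 0.0:
        frame = apply_distortion(frame, sim.distortion_k1, sim.distortion_k2)
    return frame


def pose_grid_27() -> list:
    """The factorial out-of-plane study design: 27 ground-truth poses.

    All combinations of rx in {-5, 0, 5} deg, ry in {-5, 0, 5} deg and
    tz in {-20, -10, 0} mm with the in-plane parameters zero, in row-major
    order (rx slowest, tz fastest).
    """
    return [
        RigidPose(tx=0.0, ty=0.0, tz=tz, rx=rx, ry=ry, rz=0.0)
        for rx, ry, tz in itertools.product((-5.0, 0.0, 5.0), (-5.0, 0.0, 5.0), (-20.0, -10.0, 0.0))
    ]


def default_camera() -> CameraModel:
    """The phantom study geometry: 1000/600 mm, 160x160 px at 0.5 mm pitch."""
    return CameraModel(
        source_to_detector_distance=1000.0,
        source_to_object_distance=600.0,
        detector_pixel_pitch=0.5,
        detector_size=(160, 160),
    )
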