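"""Reading and writing the pipeline's on-disk formats.

Volumes go through nibabel (NIfTI) or SimpleITK (MetaImage); frames are
16-bit PNG/TIFF via imageio; poses and traces are CSV via pandas; camera
and registration settings are YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .geometry import CameraModel, RigidPose, Volume3D
from .projection import Image2D
from .registration import (
    GaussNewtonConfig,
    PreprocessConfig,
    RegistrationConfig,
    SearchRange,
    SearchRange1D,
)

POSE_COLUMNS = ["frame_id", "tx", "ty", "tz", "rx", "ry", "rz"]


def save_volume(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    suffix = "".join(path.suffixes)
    if suffix in (".nii", ".nii.gz"):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.voxels, affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path) -> Volume3D:
    path = Path(path)
    suffix = "".join(path.suffixes)
    if suffix in (".nii", ".nii.gz"):
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return Volume3D(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        vox = sitk.GetArrayFromImage(img).T
        return Volume3D(vox, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"unsupported volume format: {path.name}")


def save_frame(image: Image2D, path) -> None:
    """Write a frame as 16-bit PNG/TIFF, clipping to [0, 1]."""
    px = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(str(path), (px * 65535).astype(np.uint16))


def load_frame(path, pitch: float) -> Image2D:
    """Read a grayscale 8/16-bit frame and rescale to [0, 1]."""
    raw = np.asarray(iio.imread(str(path)), dtype=float)
    if raw.ndim == 3:
        raw = raw.mean(axis=2)
    scale = 65535.0 if raw.max() > 255 else 255.0
    return Image2D(raw / scale, pitch)


def poses_to_csv(poses: list, path, frame_ids=None) -> None:
    if frame_ids is None:
        frame_ids = list(range(len(poses)))
    rows = [
        [fid, p.tx, p.ty, p.tz, p.rx, p.ry, p.rz] for fid, p in zip(frame_ids, poses)
    ]
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(path, index=False)


def poses_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        RigidPose(r.tx, r.ty, r.tz, r.rx, r.ry, r.rz) for r in df.itertuples(index=False)
    ]


def camera_to_yaml(camera: CameraModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"camera": camera.to_dict()}, fh)


def camera_from_yaml(path) -> CameraModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return CameraModel.from_dict(doc["camera"] if "camera" in doc else doc)


def _range_to_list(r):
    return None if r is None else [r.lo, r.hi, r.step]


def _range_from_list(v):
    return None if v is None else SearchRange1D(*v)


def config_to_dict(config: RegistrationConfig) -> dict:
    def ranges(sr: SearchRange):
        return {
            name: _range_to_list(getattr(sr, name))
            for name in ("tx", "ty", "tz", "rx", "ry", "rz")
            if getattr(sr, name) is not None
        }

    return {
        "coarse": ranges(config.coarse),
        "fine": ranges(config.fine),
        "rxry": ranges(config.rxry),
        "bins": config.bins,
        "preprocess": asdict(config.preprocess),
        "gn": asdict(config.gn),
        "drr_step_mm": config.drr_step_mm,
        "exact_coarse": config.exact_coarse,
    }


def config_from_dict(doc: dict) -> RegistrationConfig:
    base = RegistrationConfig()

    def ranges(d, default):
        if d is None:
            return default
        kw = {k: _range_from_list(v) for k, v in d.items()}
        return SearchRange(**kw)

    return RegistrationConfig(
        coarse=ranges(doc.get("coarse"), base.coarse),
        fine=ranges(doc.get("fine"), base.fine),
        rxry=ranges(doc.get("rxry"), base.rxry),
        bins=int(doc.get("bins", base.bins)),
        preprocess=PreprocessConfig(**doc.get("preprocess", {})),
        gn=GaussNewtonConfig(**doc.get("gn", {})),
        drr_step_mm=doc.get("drr_step_mm"),
        exact_coarse=bool(doc.get("exact_coarse", False)),
    )


def config_to_yaml(config: RegistrationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh)


def config_from_yaml(path) -> RegistrationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
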