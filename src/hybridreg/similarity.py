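"""The two multimodal similarity measures: EPD and SCV.

Edge position difference (EPD) scores a set of edge pixels of the moving
image (the DRR) against a precomputed chamfer distance map of the reference
(fluoroscopy) edges: the mean distance-to-nearest-edge of the transformed
edge points.  Its cost per candidate transform is proportional to the
number of edge points, which is what makes the coarse full search cheap.

Sum of conditional variance (SCV) partitions pixels by one image's
intensity bin and pools, over bins, the variance of the other image's
intensities within the bin.  It is zero exactly when one image is a
deterministic function of the other, which makes it suitable for
modalities related by an unknown monotone (or arbitrary) intensity map.
Both measures are minimised: lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import epd_batch
from .preprocess import DistanceImage, EdgeImage, EmptyEdgeImageError
from .projection import Image2D


class DegenerateImageError(ValueError):
    """A constant image has no intensity range to bin."""


@dataclass(frozen=True)
class SimilarityValue:
    """A similarity score (lower is better) and its support size."""

    value: float
    n_support: int

    def __post_init__(self):
        if self.value < 0 and self.value > -1e-12:
            object.__setattr__(self, "value", 0.0)


@dataclass(frozen=True)
class JointHistogram:
    """2-D intensity co-occurrence counts over (reference bin, moving bin)."""

    counts: np.ndarray
    ref_range: tuple
    mov_range: tuple
    bins: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def epd(
    moving_edges: EdgeImage,
    reference_distance: DistanceImage,
    inplane: tuple = (0.0, 0.0, 0.0),
    center: tuple | None = None,
) -> SimilarityValue:
    """Edge-position-difference under an in-plane transform.

    ``inplane`` is ``(tx_px, ty_px, rz_deg)``: the moving edge coordinates
    rotate by ``rz`` about ``center`` (image centre by default) and then
    translate, and the reference distance map is sampled bilinearly at the
    transformed positions.  Points leaving the map are clamped to the
    border and penalised by the out-of-bounds travel distance, which keeps
    the measure continuous and discourages sliding the edge set off the
    image.
    """
    pts = moving_edges.points()
    if pts.shape[0] == 0:
        raise EmptyEdgeImageError("EPD needs at least one moving edge pixel")
    tx_px, ty_px, rz_deg = inplane
    h, w = reference_distance.shape
    if center is None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cy, cx = center
    out = np.empty(1)
    epd_batch(
        np.ascontiguousarray(pts[:, 0]),
        np.ascontiguousarray(pts[:, 1]),
        reference_distance.values,
        np.array([float(ty_px)]),
        np.array([float(tx_px)]),
        np.array([math.radians(rz_deg)]),
        float(cy),
        float(cx),
        out,
    )
    return SimilarityValue(float(out[0]), pts.shape[0])


def epd_candidates(
    moving_edges: EdgeImage,
    reference_distance: DistanceImage,
    tx_px,
    ty_px,
    rz_deg,
    center: tuple | None = None,
) -> np.ndarray:
    """Vectorised EPD over parallel arrays of candidate in-plane transforms."""
    pts = moving_edges.points()
    if pts.shape[0] == 0:
        raise EmptyEdgeImageError("EPD needs at least one moving edge pixel")
    h, w = reference_distance.shape
    if center is None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cy, cx = center
    tx = np.asarray(tx_px, dtype=float)
    out = np.empty(tx.shape[0])
    epd_batch(
        np.ascontiguousarray(pts[:, 0]),
        np.ascontiguousarray(pts[:, 1]),
        reference_distance.values,
        np.asarray(ty_px, dtype=float),
        tx,
        np.radians(np.asarray(rz_deg, dtype=float)),
        float(cy),
        float(cx),
        out,
    )
    return out


def _bin_indices(pixels: np.ndarray, bins: int):
    lo = pixels.min()
    hi = pixels.max()
    if hi == lo:
        raise DegenerateImageError("constant image: zero intensity range")
    idx = np.floor((pixels - lo) * (bins / (hi - lo))).astype(np.int64)
    np.clip(idx, 0, bins - 1, out=idx)
    return idx, (float(lo), float(hi))


def joint_histogram(reference: Image2D, moving: Image2D, bins: int = 32) -> JointHistogram:
    """Joint intensity histogram with uniform bins over each image's range."""
    if reference.shape != moving.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("need at least two bins")
    ri, rrange = _bin_indices(reference.pixels.ravel(), bins)
    mi, mrange = _bin_indices(moving.pixels.ravel(), bins)
    counts = np.bincount(ri * bins + mi, minlength=bins * bins).reshape(bins, bins)
    return JointHistogram(counts, rrange, mrange, bins)


def _conditional_means(ref_flat, mov_idx, bins):
    counts = np.bincount(mov_idx, minlength=bins)
    sums = np.bincount(mov_idx, weights=ref_flat, minlength=bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means, counts


def scv(reference: Image2D, moving: Image2D, bins: int = 32) -> SimilarityValue:
    """Sum of conditional variance, conditioning on the moving image's bins.

    Value is ``(1/N) sum_b sum_{x in b} (ref(x) - mu_b)^2`` where ``mu_b``
    is the mean reference intensity within moving-image bin ``b``.
    """
    if reference.shape != moving.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("need at least two bins")
    ref = reference.pixels.ravel()
    mov_idx, _ = _bin_indices(moving.pixels.ravel(), bins)
    means, _ = _conditional_means(ref, mov_idx, bins)
    resid = ref - means[mov_idx]
    return SimilarityValue(float(np.mean(resid * resid)), ref.size)


def expected_image(reference: Image2D, moving: Image2D, bins: int = 32) -> Image2D:
    """Reference image remapped onto the moving image's intensity scale.

    Every pixel receives the conditional mean of the reference intensities
    within its moving-image bin; by construction the mean squared
    difference between this image and the reference equals the SCV value.
    """
    if reference.shape != moving.shape:
        raise ValueError("images must share a shape")
    ref = reference.pixels.ravel()
    mov_idx, _ = _bin_indices(moving.pixels.ravel(), bins)
    means, _ = _conditional_means(ref, mov_idx, bins)
    return Image2D(means[mov_idx].reshape(reference.shape), reference.pitch)


def scv_residual(reference: Image2D, moving: Image2D, bins: int = 32) -> np.ndarray:
    """Flattened residual ``reference - expected_image``; mean square = SCV."""
    ref = reference.pixels.ravel()
    mov_idx, _ = _bin_indices(moving.pixels.ravel(), bins)
    means, _ = _conditional_means(ref, mov_idx, bins)
    return ref - means[mov_idx]
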