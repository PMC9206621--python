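"""The three-stage hybrid registration driver.

Stage 1 (coarse, EPD): exhaustive search over a wide in-plane grid
(tx, ty, rz).  The DRR and its Canny edge set are computed once at the
initial pose; every candidate merely transforms the 2-D edge coordinates
and samples the precomputed chamfer distance map of the fluoroscopy
edges.  Under perspective this is approximate — magnification varies with
depth — but depth is fixed during this stage and the error is second
order; it is what makes the stage fast.  An exact re-projecting variant is
available behind ``exact=True`` for validation.

Stage 2 (fine in-plane, SCV): exhaustive search over a narrow in-plane
grid; each candidate re-projects the volume and scores the DRR against
the fluoroscopy with the SCV measure (both taken through the configured
pre-filter; see PreprocessConfig.scv_prefilter).

Stage 3 (final, SCV + Gauss-Newton): a grid over the out-of-plane
rotations (rx, ry); inside each cell a damped Gauss-Newton iteration
refines (tx, ty, rz, tz) on the SCV objective.  The cell with the lowest
final SCV wins.

All grid searches break ties toward the candidate closest to the stage's
initial pose (then lexicographically), so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CameraModel, RigidPose, Volume3D, project_point
from .preprocess import (
    EmptyEdgeImageError,
    canny_edges,
    chamfer_distance,
    log_filter,
)
from .projection import Image2D, PROJECTION_COUNTER, project_drr
from .similarity import (
    DegenerateImageError,
    SimilarityValue,
    epd,
    epd_candidates,
    scv,
    scv_residual,
)


class RegistrationFailure(RuntimeError):
    """No search cell produced a usable registration; traces attached."""

    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces


@dataclass(frozen=True)
class SearchRange1D:
    """Inclusive (lo, hi) search interval with a positive step, mm or deg."""

    lo: float
    hi: float
    step: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("search range requires lo <= hi")
        if self.step <= 0:
            raise ValueError("search step must be strictly positive")

    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step))
        vals = self.lo + self.step * np.arange(n + 1)
        return vals[vals <= self.hi + 1e-9]

    def contains(self, other: "SearchRange1D") -> bool:
        return self.lo < other.lo and self.hi > other.hi


@dataclass(frozen=True)
class SearchRange:
    """Per-parameter search offsets relative to a stage's initial pose."""

    tx: SearchRange1D | None = None
    ty: SearchRange1D | None = None
    tz: SearchRange1D | None = None
    rx: SearchRange1D | None = None
    ry: SearchRange1D | None = None
    rz: SearchRange1D | None = None


@dataclass(frozen=True)
class PreprocessConfig:
    """Edge/intensity preprocessing knobs shared by the stages.

    ``scv_prefilter`` selects the intensity domain of the SCV stages:
    ``"none"`` scores raw intensities — the right choice when the two
    modalities are related by a pixelwise map and the background is clean,
    as in the synthetic study — while ``"log"`` band-passes both images
    first, which suppresses structured background (soft tissue, shading)
    in real fluoroscopy at the cost of weakening the pixelwise
    relationship that SCV exploits.
    """

    canny_low: float = 0.1
    canny_high: float = 0.25
    canny_sigma: float = 1.5
    log_sigma: float = 2.0
    scv_prefilter: str = "none"  # "none" | "log"

    def scv_image(self, image: Image2D) -> Image2D:
        if self.scv_prefilter == "log":
            return log_filter(image, self.log_sigma)
        if self.scv_prefilter == "none":
            return image
        raise ValueError(f"unknown scv_prefilter: {self.scv_prefilter!r}")


@dataclass(frozen=True)
class GaussNewtonConfig:
    """Damped Gauss-Newton settings for the (tx, ty, rz, tz) refinement."""

    fd_step_mm: float = 0.5
    fd_step_deg: float = 0.5
    tol: float = 1e-3  # mixed mm/deg step-norm stopping threshold
    max_iter: int = 30
    lam0: float = 1e-3
    lam_factor: float = 10.0
    lam_max: float = 1e8


@dataclass(frozen=True)
class RegistrationConfig:
    coarse: SearchRange = field(
        default_factory=lambda: SearchRange(
            tx=SearchRange1D(-20, 20, 1.0),
            ty=SearchRange1D(-20, 20, 1.0),
            rz=SearchRange1D(-10, 10, 1.0),
            tz=SearchRange1D(-20, 0, 1.0),  # depth prior; used only for
            # sizing the hypothetical single-stage full search
        )
    )
    fine: SearchRange = field(
        default_factory=lambda: SearchRange(
            tx=SearchRange1D(-2, 2, 0.5),
            ty=SearchRange1D(-2, 2, 0.5),
            rz=SearchRange1D(-2, 2, 0.5),
            tz=SearchRange1D(-2, 2, 0.5),  # resolution reference only
        )
    )
    rxry: SearchRange = field(
        default_factory=lambda: SearchRange(
            rx=SearchRange1D(-10, 10, 5.0),
            ry=SearchRange1D(-10, 10, 5.0),
        )
    )
    bins: int = 64
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gn: GaussNewtonConfig = field(default_factory=GaussNewtonConfig)
    drr_step_mm: float | None = None
    exact_coarse: bool = False

    def __post_init__(self):
        for name in ("tx", "ty", "rz"):
            c = getattr(self.coarse, name)
            f = getattr(self.fine, name)
            if c is None or f is None or not c.contains(f):
                raise ValueError(
                    f"coarse {name} range must strictly contain the fine range"
                )


def default_config() -> RegistrationConfig:
    return RegistrationConfig()


@dataclass
class StageTrace:
    """Search trace of one stage: candidate parameters and their similarity."""

    stage: str
    param_names: tuple
    candidates: np.ndarray
    values: np.ndarray
    evaluations: int
    drr_projections: int

    def best(self):
        i = int(np.argmin(self.values))
        return self.candidates[i], float(self.values[i])


@dataclass
class RegistrationResult:
    pose: RigidPose
    final_similarity: SimilarityValue
    stage_traces: list
    converged: bool
    evaluations: dict


def _argmin_tiebreak(values: np.ndarray, offsets: np.ndarray) -> int:
    """Index of the minimum; ties go to the candidate nearest the stage's
    initial pose (smallest offset norm), then lexicographically."""
    vmin = values.min()
    tie = np.flatnonzero(values <= vmin)
    if tie.size == 1:
        return int(tie[0])
    norms = np.linalg.norm(offsets[tie], axis=1)
    order = np.lexsort(tuple(offsets[tie].T[::-1]) + (norms,))
    return int(tie[order[0]])


def _inplane_px_scale(camera: CameraModel, pose: RigidPose) -> float:
    """Detector pixels per mm of in-plane translation at the pose's depth."""
    z = camera.source_to_object_distance + pose.tz
    return (camera.source_to_detector_distance / z) / camera.detector_pixel_pitch


def coarse_inplane_epd(
    volume: Volume3D,
    camera: CameraModel,
    frame: Image2D,
    init_pose: RigidPose,
    ranges: SearchRange | None = None,
    pre: PreprocessConfig | None = None,
    drr_step_mm: float | None = None,
    exact: bool = False,
    return_trace: bool = False,
):
    """Coarse in-plane full search with the EPD measure.

    Returns ``init_pose`` with (tx, ty, rz) replaced by the grid argmin.
    ``frame`` must already be distortion-corrected.
    """
    if ranges is None:
        ranges = default_config().coarse
    if pre is None:
        pre = PreprocessConfig()
    drr = project_drr(volume, init_pose, camera, drr_step_mm)
    moving_edges = canny_edges(drr, pre.canny_low, pre.canny_high, pre.canny_sigma)
    if not moving_edges.mask.any():
        raise EmptyEdgeImageError("DRR at the initial pose produced no edges")
    ref_edges = canny_edges(frame, pre.canny_low, pre.canny_high, pre.canny_sigma)
    d_r = chamfer_distance(ref_edges)

    dtx = ranges.tx.values()
    dty = ranges.ty.values()
    drz = ranges.rz.values()
    cand = np.array(np.meshgrid(dtx, dty, drz, indexing="ij")).reshape(3, -1).T
    scale = _inplane_px_scale(camera, init_pose)
    center_px = project_point(
        camera,
        [init_pose.tx, init_pose.ty, camera.source_to_object_distance + init_pose.tz],
    )
    n0 = PROJECTION_COUNTER.count
    if exact:
        values = np.empty(cand.shape[0])
        for i, (ox, oy, oz_rz) in enumerate(cand):
            pc = replace(init_pose, tx=init_pose.tx + ox, ty=init_pose.ty + oy,
                         rz=init_pose.rz + oz_rz)
            drr_c = project_drr(volume, pc, camera, drr_step_mm)
            edges_c = canny_edges(drr_c, pre.canny_low, pre.canny_high, pre.canny_sigma)
            values[i] = epd(edges_c, d_r).value
    else:
        values = epd_candidates(
            moving_edges,
            d_r,
            tx_px=cand[:, 0] * scale,
            ty_px=cand[:, 1] * scale,
            rz_deg=cand[:, 2],
            center=(center_px[0], center_px[1]),
        )
    i = _argmin_tiebreak(values, cand)
    best = replace(
        init_pose,
        tx=init_pose.tx + cand[i, 0],
        ty=init_pose.ty + cand[i, 1],
        rz=init_pose.rz + cand[i, 2],
    )
    trace = StageTrace(
        "coarse_epd",
        ("tx", "ty", "rz"),
        cand,
        values,
        cand.shape[0],
        PROJECTION_COUNTER.count - n0 + 1,
    )
    return (best, trace) if return_trace else best


def inplane_scv(
    volume: Volume3D,
    camera: CameraModel,
    frame: Image2D,
    init_pose: RigidPose,
    ranges: SearchRange | None = None,
    bins: int = 64,
    pre: PreprocessConfig | None = None,
    drr_step_mm: float | None = None,
    return_trace: bool = False,
):
    """Narrow in-plane full search with the SCV measure.

    Every candidate re-projects the volume and scores the DRR against the
    fluoroscopy with SCV, both taken through the configured pre-filter.
    """
    if ranges is None:
        ranges = default_config().fine
    if pre is None:
        pre = PreprocessConfig()
    fl = pre.scv_image(frame)
    dtx = ranges.tx.values()
    dty = ranges.ty.values()
    drz = ranges.rz.values()
    cand = np.array(np.meshgrid(dtx, dty, drz, indexing="ij")).reshape(3, -1).T
    values = np.empty(cand.shape[0])
    n0 = PROJECTION_COUNTER.count
    for i, (ox, oy, orz) in enumerate(cand):
        pc = replace(
            init_pose,
            tx=init_pose.tx + ox,
            ty=init_pose.ty + oy,
            rz=init_pose.rz + orz,
        )
        drr = project_drr(volume, pc, camera, drr_step_mm)
        try:
            dl = pre.scv_image(drr)
            values[i] = scv(fl, dl, bins).value
        except DegenerateImageError as exc:
            raise DegenerateImageError(
                "LoG-filtered DRR is constant; candidate pose leaves the field of view"
            ) from exc
    i = _argmin_tiebreak(values, cand)
    best = replace(
        init_pose,
        tx=init_pose.tx + cand[i, 0],
        ty=init_pose.ty + cand[i, 1],
        rz=init_pose.rz + cand[i, 2],
    )
    trace = StageTrace(
        "inplane_scv",
        ("tx", "ty", "rz"),
        cand,
        values,
        cand.shape[0],
        PROJECTION_COUNTER.count - n0,
    )
    return (best, trace) if return_trace else best


def _scv_cost(volume, camera, fl, pose, bins, pre, drr_step_mm):
    drr = project_drr(volume, pose, camera, drr_step_mm)
    dl = pre.scv_image(drr)
    return scv_residual(fl, dl, bins)


def gauss_newton_refine(
    volume: Volume3D,
    camera: CameraModel,
    frame: Image2D,
    pose: RigidPose,
    bins: int = 64,
    pre: PreprocessConfig | None = None,
    gn: GaussNewtonConfig | None = None,
    drr_step_mm: float | None = None,
):
    """Damped Gauss-Newton refinement of (tx, ty, rz, tz) at fixed (rx, ry).

    The residual is the per-pixel difference between the (pre-filtered)
    fluoroscopy and its expected image conditioned on the current DRR's
    intensity bins, so the summed squared residual equals N times the SCV
    value being minimised.  The Jacobian is built by central finite
    differences; a Levenberg damping parameter grows on rejected steps so
    the accepted-step SCV sequence is non-increasing by construction.

    Returns ``(pose, SimilarityValue, info)`` where ``info`` carries the
    accepted SCV trace and the convergence flag.
    """
    if pre is None:
        pre = PreprocessConfig()
    if gn is None:
        gn = GaussNewtonConfig()
    fl = pre.scv_image(frame)

    def resid(p):
        pc = replace(pose, tx=p[0], ty=p[1], rz=p[2], tz=p[3])
        return _scv_cost(volume, camera, fl, pc, bins, pre, drr_step_mm)

    p = np.array([pose.tx, pose.ty, pose.rz, pose.tz])
    steps = np.array([gn.fd_step_mm, gn.fd_step_mm, gn.fd_step_deg, gn.fd_step_mm])
    r = resid(p)
    s_cur = float(np.mean(r * r))
    trace = [s_cur]
    lam = gn.lam0
    converged = False
    for _ in range(gn.max_iter):
        jac = np.empty((r.size, 4))
        for k in range(4):
            ph = p.copy()
            ph[k] += steps[k]
            pl = p.copy()
            pl[k] -= steps[k]
            jac[:, k] = (resid(ph) - resid(pl)) / (2 * steps[k])
        jtj = jac.T @ jac
        jtr = jac.T @ r
        # Marquardt scaling: damp relative to each parameter's own curvature
        # so the weakly observable depth direction is not throttled
        scale = np.diag(np.maximum(np.diag(jtj), 1e-30))
        accepted = False
        delta = np.zeros(4)
        while lam <= gn.lam_max:
            try:
                delta = np.linalg.solve(jtj + lam * scale, -jtr)
            except np.linalg.LinAlgError:
                lam *= gn.lam_factor
                continue
            p_try = p + delta
            try:
                r_try = resid(p_try)
            except DegenerateImageError:
                lam *= gn.lam_factor
                continue
            s_try = float(np.mean(r_try * r_try))
            if s_try <= s_cur:
                p, r, s_cur = p_try, r_try, s_try
                trace.append(s_cur)
                lam = max(lam / gn.lam_factor, 1e-12)
                accepted = True
                break
            lam *= gn.lam_factor
        if not accepted:
            break  # damping exhausted without decrease: return last accepted
        if np.linalg.norm(delta) < gn.tol:
            converged = True
            break
    refined = replace(pose, tx=p[0], ty=p[1], rz=p[2], tz=p[3])
    info = {"scv_trace": np.array(trace), "converged": converged}
    return refined, SimilarityValue(s_cur, r.size), info


def final_registration(
    volume: Volume3D,
    camera: CameraModel,
    frame: Image2D,
    init_pose: RigidPose,
    rxry: SearchRange | None = None,
    bins: int = 64,
    pre: PreprocessConfig | None = None,
    gn: GaussNewtonConfig | None = None,
    drr_step_mm: float | None = None,
) -> RegistrationResult:
    """Out-of-plane (rx, ry) grid search with Gauss-Newton inside each cell."""
    if rxry is None:
        rxry = default_config().rxry
    drx = rxry.rx.values()
    dry = rxry.ry.values()
    cells = np.array(np.meshgrid(drx, dry, indexing="ij")).reshape(2, -1).T
    n0 = PROJECTION_COUNTER.count
    poses, sims, convs, traces = [], [], [], []
    values = np.empty(cells.shape[0])
    for i, (ox, oy) in enumerate(cells):
        cell_pose = replace(init_pose, rx=init_pose.rx + ox, ry=init_pose.ry + oy)
        try:
            refined, sim, info = gauss_newton_refine(
                volume, camera, frame, cell_pose, bins, pre, gn, drr_step_mm
            )
        except DegenerateImageError:
            refined, sim, info = cell_pose, None, {"converged": False, "scv_trace": None}
        poses.append(refined)
        sims.append(sim)
        convs.append(info["converged"])
        traces.append(info.get("scv_trace"))
        values[i] = np.inf if sim is None else sim.value
    if not np.any(np.isfinite(values)):
        raise RegistrationFailure("every (rx, ry) cell failed", traces)
    i = _argmin_tiebreak(values, cells)
    trace = StageTrace(
        "final_scv_gn",
        ("rx", "ry"),
        cells,
        values,
        cells.shape[0],
        PROJECTION_COUNTER.count - n0,
    )
    return RegistrationResult(
        pose=poses[i],
        final_similarity=sims[i],
        stage_traces=[trace],
        converged=bool(convs[i]),
        evaluations={"final_scv_gn": trace.drr_projections},
    )


def hybrid_register(
    volume: Volume3D,
    camera: CameraModel,
    frame: Image2D,
    init_pose: RigidPose,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Full pipeline: EPD coarse -> SCV in-plane -> (rx, ry) + Gauss-Newton.

    ``frame`` must be distortion-corrected.  Each stage is seeded by the
    previous stage's pose.
    """
    if config is None:
        config = default_config()
    pose1, t1 = coarse_inplane_epd(
        volume,
        camera,
        frame,
        init_pose,
        config.coarse,
        config.preprocess,
        config.drr_step_mm,
        exact=config.exact_coarse,
        return_trace=True,
    )
    pose2, t2 = inplane_scv(
        volume,
        camera,
        frame,
        pose1,
        config.fine,
        config.bins,
        config.preprocess,
        config.drr_step_mm,
        return_trace=True,
    )
    result = final_registration(
        volume,
        camera,
        frame,
        pose2,
        config.rxry,
        config.bins,
        config.preprocess,
        config.gn,
        config.drr_step_mm,
    )
    result.stage_traces = [t1, t2] + result.stage_traces
    result.evaluations = {
        "coarse_epd": t1.evaluations,
        "coarse_epd_drr": t1.drr_projections,
        "inplane_scv_drr": t2.drr_projections,
        "final_scv_gn_drr": result.evaluations["final_scv_gn"],
        "total_drr": t1.drr_projections
        + t2.drr_projections
        + result.evaluations["final_scv_gn"],
    }
    return result


def register_sequence(
    volume: Volume3D,
    camera: CameraModel,
    frames: list,
    init_pose: RigidPose,
    config: RegistrationConfig | None = None,
) -> list:
    """Register a frame sequence, chaining each result into the next init."""
    results = []
    pose = init_pose
    for frame in frames:
        res = hybrid_register(volume, camera, frame, pose, config)
        results.append(res)
        pose = res.pose
    return results


def pure_scv_search_size(config: RegistrationConfig | None = None) -> int:
    """Grid size of a hypothetical single-stage SCV full search.

    Covers the coarse (tx, ty, rz, tz) spans at the fine stage's
    resolution together with the (rx, ry) grid — the number of DRR
    projections an exhaustive six-parameter SCV search would need, used as
    the denominator of the hybrid pipeline's counter-based speed-up.
    """
    if config is None:
        config = default_config()
    n = 1
    for name in ("tx", "ty", "rz", "tz"):
        c = getattr(config.coarse, name)
        f = getattr(config.fine, name)
        if c is None or f is None:
            continue
        n *= int(round((c.hi - c.lo) / f.step)) + 1
    for name in ("rx", "ry"):
        r = getattr(config.rxry, name)
        if r is not None:
            n *= r.values().size
    return n
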