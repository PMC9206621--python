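"""Stage-level contracts of the hybrid registration driver.

Uses a coarse 96x96 detector and reduced search grids so each test stays
cheap; the full-scale study lives in the acceptance tests.
"""

import numpy as np
import pytest

from hybridreg.geometry import RigidPose
from hybridreg.phantom import FluoroSimSpec, simulate_fluoroscopy
from hybridreg.projection import PROJECTION_COUNTER
from hybridreg.registration import (
    GaussNewtonConfig,
    PreprocessConfig,
    RegistrationConfig,
    SearchRange,
    SearchRange1D,
    coarse_inplane_epd,
    default_config,
    final_registration,
    gauss_newton_refine,
    hybrid_register,
    inplane_scv,
    pure_scv_search_size,
)


@pytest.fixture(scope="module")
def frame_at(small_volume, small_camera):
    def make(pose, noise=0.0, seed=0):
        return simulate_fluoroscopy(
            small_volume,
            pose,
            small_camera,
            FluoroSimSpec(noise_sigma=noise, rng_seed=seed),
        )

    return make


SMALL_COARSE = SearchRange(
    tx=SearchRange1D(-6, 6, 1.0),
    ty=SearchRange1D(-6, 6, 1.0),
    rz=SearchRange1D(-6, 6, 1.0),
)
SMALL_FINE = SearchRange(
    tx=SearchRange1D(-1.5, 1.5, 0.5),
    ty=SearchRange1D(-1.5, 1.5, 0.5),
    rz=SearchRange1D(-1.5, 1.5, 0.5),
)


class TestSearchRange:
    def test_values_inclusive(self):
        assert np.allclose(SearchRange1D(-2, 2, 1).values(), [-2, -1, 0, 1, 2])

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SearchRange1D(2, -2, 1)
        with pytest.raises(ValueError):
            SearchRange1D(-2, 2, 0)

    def test_config_requires_coarse_containing_fine(self):
        with pytest.raises(ValueError):
            RegistrationConfig(
                coarse=SearchRange(
                    tx=SearchRange1D(-1, 1, 0.5),
                    ty=SearchRange1D(-20, 20, 1),
                    rz=SearchRange1D(-10, 10, 1),
                ),
            )


class TestCoarseEpd:
    def test_recovers_zero_offset_at_truth(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10)
        pose = coarse_inplane_epd(
            small_volume, small_camera, frame_at(truth), truth, SMALL_COARSE
        )
        assert np.allclose(pose.as_array(), truth.as_array(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_inplane_offset_within_one_step(
        self, small_volume, small_camera, frame_at, seed
    ):
        rng = np.random.default_rng(seed)
        truth = RigidPose(
            tx=rng.uniform(-4, 4), ty=rng.uniform(-4, 4), tz=-10, rz=rng.uniform(-4, 4)
        )
        frame = frame_at(truth, noise=0.02, seed=seed)
        init = RigidPose(tz=-10)
        pose = coarse_inplane_epd(small_volume, small_camera, frame, init, SMALL_COARSE)
        err = pose.as_array() - truth.as_array()
        # translations within one grid step; rotation gets half a step of
        # slack on this coarsely voxelised (2 mm) fixture
        assert abs(err[0]) <= 1.0 and abs(err[1]) <= 1.0 and abs(err[5]) <= 1.5

    def test_evaluation_count_is_grid_product(
        self, small_volume, small_camera, frame_at
    ):
        truth = RigidPose(tz=-10)
        _, trace = coarse_inplane_epd(
            small_volume,
            small_camera,
            frame_at(truth),
            truth,
            SMALL_COARSE,
            return_trace=True,
        )
        assert trace.evaluations == 13 * 13 * 13
        assert trace.drr_projections == 1  # single DRR for the whole stage

    def test_exact_variant_agrees_near_truth(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10)
        tiny = SearchRange(
            tx=SearchRange1D(-1, 1, 1.0),
            ty=SearchRange1D(-1, 1, 1.0),
            rz=SearchRange1D(-1, 1, 1.0),
        )
        frame = frame_at(truth)
        fast = coarse_inplane_epd(small_volume, small_camera, frame, truth, tiny)
        exact = coarse_inplane_epd(
            small_volume, small_camera, frame, truth, tiny, exact=True
        )
        assert np.allclose(fast.as_array(), exact.as_array(), atol=1e-12)


class TestInplaneScv:
    def test_single_cell_returns_init(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10)
        one = SearchRange(
            tx=SearchRange1D(0, 0, 1.0),
            ty=SearchRange1D(0, 0, 1.0),
            rz=SearchRange1D(0, 0, 1.0),
        )
        pose = inplane_scv(small_volume, small_camera, frame_at(truth), truth, one)
        assert np.allclose(pose.as_array(), truth.as_array())

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_truth_within_one_fine_step(
        self, small_volume, small_camera, frame_at, seed
    ):
        rng = np.random.default_rng(seed)
        truth = RigidPose(tx=rng.uniform(-1, 1), ty=rng.uniform(-1, 1), tz=-10)
        frame = frame_at(truth, noise=0.02, seed=seed)
        pose = inplane_scv(small_volume, small_camera, frame, RigidPose(tz=-10), SMALL_FINE)
        err = pose.as_array() - truth.as_array()
        assert abs(err[0]) <= 0.5 and abs(err[1]) <= 0.5 and abs(err[5]) <= 0.5

    def test_returned_value_not_worse_than_init(
        self, small_volume, small_camera, frame_at
    ):
        from hybridreg.similarity import scv
        from hybridreg.projection import project_drr

        truth = RigidPose(tx=0.7, tz=-10)
        frame = frame_at(truth)
        init = RigidPose(tz=-10)
        pose, trace = inplane_scv(
            small_volume, small_camera, frame, init, SMALL_FINE, return_trace=True
        )
        init_idx = np.flatnonzero(np.all(trace.candidates == 0, axis=1))[0]
        assert trace.values.min() <= trace.values[init_idx]


class TestGaussNewton:
    def test_terminates_quickly_at_truth(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10, rx=5)
        refined, sim, info = gauss_newton_refine(
            small_volume, small_camera, frame_at(truth), truth
        )
        assert len(info["scv_trace"]) <= 4  # initial value + a few tiny steps
        d = refined.as_array() - truth.as_array()
        assert np.all(np.abs(d[[0, 1]]) < 0.05) and abs(d[5]) < 0.05
        assert abs(d[2]) < 0.2  # depth drift on the coarse fixture

    def test_accepted_scv_sequence_nonincreasing(
        self, small_volume, small_camera, frame_at
    ):
        truth = RigidPose(tz=-10)
        start = RigidPose(tx=1.5, ty=-1.0, tz=-7.0, rz=1.0)
        _, _, info = gauss_newton_refine(
            small_volume, small_camera, frame_at(truth, noise=0.02), start
        )
        trace = info["scv_trace"]
        assert np.all(np.diff(trace) <= 1e-15)

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_from_offset_noiseless(
        self, small_volume, small_camera, frame_at, seed
    ):
        rng = np.random.default_rng(seed)
        truth = RigidPose(tz=-10, rx=[-5, 0, 5][seed % 3])
        start = RigidPose(
            tx=truth.tx + 2, ty=truth.ty + 2, tz=truth.tz + 5, rx=truth.rx, rz=2.0
        )
        refined, _, info = gauss_newton_refine(
            small_volume, small_camera, frame_at(truth), start
        )
        err = refined.as_array() - truth.as_array()
        assert abs(err[0]) < 0.2 and abs(err[1]) < 0.2
        assert abs(err[5]) < 0.2
        # depth is the least observable direction; the 2 mm fixture gets a
        # looser bound than the full-resolution phantom
        assert abs(err[2]) < 1.5


class TestFinalRegistration:
    def test_single_cell_equals_plain_refinement(
        self, small_volume, small_camera, frame_at
    ):
        truth = RigidPose(tz=-10, rx=5)
        frame = frame_at(truth)
        start = RigidPose(tz=-9, rx=5)
        one = SearchRange(rx=SearchRange1D(0, 0, 1.0), ry=SearchRange1D(0, 0, 1.0))
        res = final_registration(small_volume, small_camera, frame, start, one)
        refined, sim, _ = gauss_newton_refine(
            small_volume, small_camera, frame, start
        )
        assert np.allclose(res.pose.as_array(), refined.as_array(), atol=1e-12)
        assert res.final_similarity.value == pytest.approx(sim.value)

    def test_winner_is_true_rxry_cell(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10, rx=5, ry=-5)
        frame = frame_at(truth)
        start = RigidPose(tz=-10)
        grid = SearchRange(rx=SearchRange1D(-5, 5, 5.0), ry=SearchRange1D(-5, 5, 5.0))
        res = final_registration(small_volume, small_camera, frame, start, grid)
        assert res.pose.rx == 5.0 and res.pose.ry == -5.0

    def test_winner_has_minimum_similarity(self, small_volume, small_camera, frame_at):
        truth = RigidPose(tz=-10, rx=5)
        res = final_registration(
            small_volume,
            small_camera,
            frame_at(truth, noise=0.02),
            RigidPose(tz=-10),
            SearchRange(rx=SearchRange1D(-5, 5, 5.0), ry=SearchRange1D(0, 0, 1.0)),
        )
        finite = res.stage_traces[-1].values
        assert res.final_similarity.value == pytest.approx(np.min(finite))


@pytest.fixture(scope="module")
def small_config():
    return RegistrationConfig(
        coarse=SearchRange(
            tx=SearchRange1D(-6, 6, 1.0),
            ty=SearchRange1D(-6, 6, 1.0),
            rz=SearchRange1D(-6, 6, 1.0),
            tz=SearchRange1D(-20, 0, 1.0),
        ),
        fine=SMALL_FINE,
        rxry=SearchRange(rx=SearchRange1D(-5, 5, 5.0), ry=SearchRange1D(-5, 5, 5.0)),
    )


class TestHybridPipeline:

    def test_init_at_truth_is_fixed_point(
        self, small_volume, small_camera, frame_at, small_config
    ):
        truth = RigidPose(tz=-10, rx=5)
        res = hybrid_register(
            small_volume, small_camera, frame_at(truth), truth, small_config
        )
        err = np.abs(res.pose.as_array() - truth.as_array())
        assert np.all(err[[0, 1]] <= 1.0) and err[2] <= 5.0
        assert err[3] <= 2 and err[4] <= 2 and err[5] <= 1

    def test_end_to_end_recovery(self, small_volume, small_camera, frame_at, small_config):
        truth = RigidPose(tz=-10, rx=5, ry=-5)
        frame = frame_at(truth, noise=0.02, seed=3)
        init = RigidPose(tx=2.0, ty=-1.5, tz=-13.0, rz=1.0)
        res = hybrid_register(small_volume, small_camera, frame, init, small_config)
        err = np.abs(res.pose.as_array() - truth.as_array())
        assert err[0] <= 1.0 and err[1] <= 1.0 and err[2] <= 5.0
        assert err[3] <= 2.0 and err[4] <= 2.0 and err[5] <= 1.0

    def test_stage_ordering_and_projection_budget(
        self, small_volume, small_camera, frame_at, small_config
    ):
        truth = RigidPose(tz=-10)
        PROJECTION_COUNTER.reset()
        res = hybrid_register(
            small_volume, small_camera, frame_at(truth), truth, small_config
        )
        stages = [t.stage for t in res.stage_traces]
        assert stages == ["coarse_epd", "inplane_scv", "final_scv_gn"]
        # EPD candidate evaluations dwarf SCV-stage DRR projections
        assert res.evaluations["coarse_epd"] > 5 * res.evaluations["inplane_scv_drr"]
        # hybrid total is far below a single-stage SCV full search
        assert res.evaluations["total_drr"] * 3 <= pure_scv_search_size(small_config)


def test_pure_search_size_formula():
    cfg = default_config()
    # coarse spans at fine resolution: tx,ty 81 each, rz 41, tz 41; rx,ry 5 each
    assert pure_scv_search_size(cfg) == 81 * 81 * 41 * 41 * 5 * 5
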