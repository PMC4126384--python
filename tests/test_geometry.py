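"""RVE geometry: tortuosity, axon generation, clipping, volume accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonrve.config import GeometryConfig
from axonrve.errors import (
    CalibrationError,
    ConfigurationError,
    InvalidGeometryError,
)
from axonrve.geometry import (
    AxonPath,
    BoxDomain,
    RVEGeometry,
    axon_volume,
    build_rve,
    clip_to_domain,
    compute_tortuosity,
    generate_axon_path,
    partition_subsegments,
)

BOX = BoxDomain()


class TestTortuosity:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (0, 0, 5.68)], 1.0),
            ([(0, 0, 0), (0, 1, 1), (0, 0, 2)], 1.41421),
            # arc length 6.248 over chord 5.68: tortuosity 1.10
            ([(0, 0, 0), (0, 1.30146, 2.84), (0, 0, 5.68)], 1.1),
        ],
    )
    def test_examples(self, points, expected):
        assert compute_tortuosity(points) == pytest.approx(expected, abs=1e-5)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidGeometryError):
            compute_tortuosity([(0, 0, 0)])

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(InvalidGeometryError):
            compute_tortuosity([(0, 0, 0), (1, 1, 1), (0, 0, 0)])

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_never_below_one(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((12, 3)).cumsum(axis=0)
        if np.linalg.norm(pts[-1] - pts[0]) < 1e-9:
            return
        assert compute_tortuosity(pts) >= 1.0 - 1e-12


class TestGenerateAxonPath:
    def test_straight_for_unit_target(self):
        path = generate_axon_path(0, 1.0, BOX)
        assert path.tortuosity == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.diff(path.centerline[:, :2], axis=0), 0.0)

    def test_endpoints_span_z_faces(self):
        for seed in range(5):
            path = generate_axon_path(seed, 1.12, BOX)
            assert path.centerline[0, 2] == pytest.approx(0.0, abs=1e-12)
            assert path.centerline[-1, 2] == pytest.approx(BOX.size_z, abs=1e-12)

    def test_target_1p15_realized_within_band(self):
        path = generate_axon_path(7, 1.15, BOX)
        assert 1.13 <= path.tortuosity <= 1.17

    def test_reproducible_for_fixed_seed(self):
        a = generate_axon_path(42, 1.1, BOX)
        b = generate_axon_path(42, 1.1, BOX)
        assert np.array_equal(a.centerline, b.centerline)

    def test_centerline_stays_inside_box(self):
        path = generate_axon_path(11, 1.25, BOX)
        assert np.all(path.centerline >= -1e-12)
        assert np.all(path.centerline <= BOX.sizes + 1e-12)

    def test_calibration_accuracy_over_population(self):
        """Mean |realized - target| over 100 seeded axons stays below 0.02."""
        rng = np.random.default_rng(5)
        errs = []
        for seed in range(100):
            target = float(rng.uniform(1.02, 1.25))
            path = generate_axon_path(seed, target, BOX)
            errs.append(abs(path.tortuosity - target))
        assert np.mean(errs) <= 0.02

    def test_unreachable_target_names_max_attainable(self):
        with pytest.raises(CalibrationError) as err:
            generate_axon_path(0, 50.0, BOX, n_waypoints=1)
        assert err.value.max_attainable is not None
        assert err.value.max_attainable < 50.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_axon_path(0, 0.9, BOX)


def _path_from_points(points, radius=0.2):
    pts = np.asarray(points, dtype=float)
    return AxonPath(waypoints=pts, centerline=pts, radius=radius,
                    tortuosity=compute_tortuosity(pts))


class TestClipToDomain:
    def test_interior_path_unchanged(self):
        path = generate_axon_path(3, 1.1, BOX)
        clipped = clip_to_domain(path, BOX)
        assert np.array_equal(clipped.centerline, path.centerline)

    def test_out_of_bounds_coordinate_projected(self):
        path = _path_from_points([(0.2, 5.0, 0.0), (0.2, 10.3, 3.0),
                                  (0.2, 5.0, 5.68)])
        clipped = clip_to_domain(path, BOX)
        assert clipped.centerline[1, 1] == pytest.approx(10.0)

    def test_clipping_never_raises_tortuosity(self):
        """For paths whose endpoints lie inside the box (the generator's
        regime), projection onto the box is 1-Lipschitz, so the arc can only
        shrink while the chord is unchanged."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            z = np.sort(rng.uniform(0, BOX.size_z, 10))
            z[0], z[-1] = 0.0, BOX.size_z
            pts = np.column_stack([
                rng.uniform(-0.3, 0.7, 10), rng.uniform(-3, 13, 10), z
            ])
            pts[0, :2] = [0.2, 5.0]    # endpoints inside the domain
            pts[-1, :2] = [0.2, 5.0]
            path = _path_from_points(pts)
            clipped = clip_to_domain(path, BOX)
            assert clipped.tortuosity <= path.tortuosity + 1e-9


class TestAxonVolume:
    def test_straight_swept_cylinder(self):
        path = _path_from_points([(0.2, 5, 0), (0.2, 5, 5.68)])
        assert axon_volume(path) == pytest.approx(0.71377, abs=1e-5)

    def test_zero_radius(self):
        path = _path_from_points([(0.2, 5, 0), (0.2, 5, 5.68)], radius=0.0)
        assert axon_volume(path) == 0.0

    def test_undulated_arc_length_scales_volume(self):
        # arc length 1.1 * 5.68 regardless of how the path winds
        path = _path_from_points([(0.2, 5, 0), (0.2, 5, 3.0), (0.2, 5, 6.248)])
        assert axon_volume(path) == pytest.approx(0.78515, abs=1e-5)


class TestPartitionSubsegments:
    def test_fifty_equal_arc_pieces(self):
        path = generate_axon_path(9, 1.15, BOX)
        arcs = []
        seg = np.linalg.norm(np.diff(path.centerline, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arcs = np.diff(cum[path.subsegment_bounds])
        assert len(arcs) == 50
        assert np.max(np.abs(arcs - arcs.mean())) <= 0.01 * arcs.mean()
        assert arcs.sum() == pytest.approx(cum[-1], rel=1e-12)

    def test_single_piece_spans_whole_axon(self):
        path = generate_axon_path(9, 1.1, BOX)
        repart = partition_subsegments(path, n=1)
        assert repart.n_subsegments == 1
        assert repart.subsegment_bounds[0] == 0
        assert repart.subsegment_bounds[-1] == len(path.centerline) - 1

    def test_invalid_count_rejected(self):
        path = generate_axon_path(9, 1.1, BOX)
        with pytest.raises(ConfigurationError):
            partition_subsegments(path, n=0)


class TestBuildRVE:
    def test_default_population(self, default_rve):
        rve = default_rve
        assert rve.achieved_volume_fraction == pytest.approx(0.53, abs=1e-9)
        assert abs(rve.achieved_volume_fraction - 0.53) <= 0.01
        mean_und = rve.tortuosities().mean()
        assert 1.05 <= mean_und <= 1.25
        assert all(a.tortuosity >= 1.0 for a in rve.axons)
        assert all(a.n_subsegments == 50 for a in rve.axons)

    def test_volume_fraction_identity(self, default_rve):
        total = sum(axon_volume(a) for a in default_rve.axons)
        assert total / default_rve.domain.volume == pytest.approx(
            default_rve.achieved_volume_fraction, rel=1e-12
        )

    def test_zero_target_gives_zero_axons(self):
        rve = build_rve(GeometryConfig(target_volume_fraction=0.0), seed=1)
        assert rve.n_axons == 0
        assert rve.achieved_volume_fraction == 0.0

    def test_fraction_above_packing_bound_rejected(self):
        with pytest.raises((ConfigurationError, ValueError)):
            build_rve(GeometryConfig(target_volume_fraction=0.9), seed=1)

    def test_same_seed_bitwise_identical_serialization(self):
        cfg = GeometryConfig(target_volume_fraction=0.1)
        a = build_rve(cfg, seed=5).to_json()
        b = build_rve(cfg, seed=5).to_json()
        assert a == b

    def test_json_round_trip(self, sparse_rve):
        text = sparse_rve.to_json()
        back = RVEGeometry.from_json(text)
        assert back.to_json() == text
        assert back.n_axons == sparse_rve.n_axons
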