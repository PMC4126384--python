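"""FE forward solver: meshing, embedding, assembly consistency, physics."""

import numpy as np
import pytest

from axonrve.config import GeometryConfig
from axonrve.constitutive import OgdenMaterial, uniaxial_nominal_stress
from axonrve.errors import ConfigurationError, InvalidGeometryError
from axonrve.fe import (
    LoadProgram,
    MaterialSet,
    RVEModel,
    homogenized_nominal_stress,
    initial_state,
    locate_host_and_weights,
    mesh_box,
    newton_solve,
    staged_simulation,
    tortuosity_trace,
    volume_averaged_p33,
    von_mises_field,
)
from axonrve.geometry import (
    BoxDomain,
    RVEGeometry,
    axon_volume,
    build_rve,
    generate_axon_path,
)


def empty_rve(domain=BoxDomain()):
    return RVEGeometry(domain=domain, axons=(), target_volume_fraction=0.0,
                       achieved_volume_fraction=0.0, seed=0)


def single_axon_rve(target_tortuosity, seed=4, domain=BoxDomain()):
    path = generate_axon_path(seed, target_tortuosity, domain)
    vf = axon_volume(path) / domain.volume
    return RVEGeometry(domain=domain, axons=(path,), target_volume_fraction=vf,
                       achieved_volume_fraction=vf, seed=seed)


class TestMeshBox:
    def test_unit_cube_half_size(self):
        mesh = mesh_box(BoxDomain(1, 1, 1), 0.5)
        assert mesh.counts == (2, 2, 2)
        assert mesh.n_elements == 8
        assert mesh.n_nodes == 27

    def test_single_element_box(self):
        mesh = mesh_box(BoxDomain(1, 1, 1), 2.0)
        assert mesh.n_elements == 1
        assert mesh.n_nodes == 8

    def test_default_box_rounding_rule(self):
        mesh = mesh_box(BoxDomain(), 0.2)
        assert mesh.counts == (2, 50, 28)
        assert mesh.n_elements == 2800

    def test_face_sets(self):
        mesh = mesh_box(BoxDomain(1, 1, 1), 0.5)
        assert len(mesh.z0_nodes) == 9
        assert len(mesh.z1_nodes) == 9
        assert np.allclose(mesh.nodes[mesh.z1_nodes][:, 2], 1.0)


class TestLocateHostAndWeights:
    def test_element_centroid_gets_equal_weights(self):
        mesh = mesh_box(BoxDomain(1, 1, 1), 0.5)
        _, _, w = locate_host_and_weights([0.25, 0.25, 0.25], mesh)
        assert np.allclose(w, 0.125)

    def test_mesh_node_gets_unit_weight(self):
        mesh = mesh_box(BoxDomain(1, 1, 1), 0.5)
        _, nids, w = locate_host_and_weights([0.5, 0.5, 0.5], mesh)
        assert np.isclose(w.max(), 1.0)
        assert np.isclose(w.sum(), 1.0)
        node = nids[np.argmax(w)]
        assert np.allclose(mesh.nodes[node], [0.5, 0.5, 0.5])

    def test_partition_of_unity_and_interpolation(self):
        mesh = mesh_box(BoxDomain(), 0.4)
        rng = np.random.default_rng(1)
        for p in rng.uniform([0, 0, 0], mesh.domain.sizes, size=(30, 3)):
            _, nids, w = locate_host_and_weights(p, mesh)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= -1e-12)
            # trilinear weights must reproduce the point itself
            assert np.allclose(w @ mesh.nodes[nids], p, atol=1e-9)

    def test_outside_point_rejected(self):
        mesh = mesh_box(BoxDomain(), 0.4)
        with pytest.raises(InvalidGeometryError):
            locate_host_and_weights([0.2, 11.0, 2.0], mesh)


@pytest.fixture(scope="module")
def sparse_model(sparse_rve, material_set):
    return RVEModel(sparse_rve, material_set, element_size=0.5)


class TestAssembly:

    def test_reference_state_has_zero_residual(self, sparse_model):
        model = sparse_model
        st = initial_state(model)
        r, _ = model.assemble(st.u, st.ties, with_tangent=False)
        assert np.linalg.norm(r[model.free_mask]) < 1e-10

    def test_tangent_is_symmetric(self, sparse_model, rng):
        model = sparse_model
        st = initial_state(model)
        u = 0.02 * rng.standard_normal(model.n_dof)
        _, K = model.assemble(u, st.ties)
        diff = (K - K.T).tocoo()
        denom = max(abs(K.max()), abs(K.min()))
        assert (np.abs(diff.data).max() if diff.nnz else 0.0) <= 1e-8 * denom

    def test_tangent_matches_residual_directional_derivative(self, sparse_model, rng):
        model = sparse_model
        st = initial_state(model)
        u = 0.02 * rng.standard_normal(model.n_dof)
        r, K = model.assemble(u, st.ties)
        d = rng.standard_normal(model.n_dof)
        d /= np.linalg.norm(d)
        h = 1e-6
        rp, _ = model.assemble(u + h * d, st.ties, with_tangent=False)
        rm, _ = model.assemble(u - h * d, st.ties, with_tangent=False)
        fd = (rp - rm) / (2 * h)
        Kd = K @ d
        assert np.linalg.norm(fd - Kd) <= 1e-5 * np.linalg.norm(Kd)


class TestNewtonSolve:
    def test_already_at_target_performs_no_iterations(self, material_set):
        model = RVEModel(empty_rve(), material_set, element_size=0.5)
        st = initial_state(model)
        out = newton_solve(st, 1.0, substeps=3)
        assert out.newton_iterations == 0
        assert np.allclose(out.u, 0.0)

    def test_homogeneous_matrix_matches_closed_form(self, tissue_material):
        mats = MaterialSet.from_axon_modulus(3 * 32.8, 8.22)  # ECM mu = 32.8
        model = RVEModel(empty_rve(), mats, element_size=0.5)
        st = initial_state(model)
        newton_solve(st, 1.06, substeps=3)
        s_fe = homogenized_nominal_stress(st)
        s_cf = uniaxial_nominal_stress(1.06, tissue_material)
        assert s_fe == pytest.approx(s_cf, rel=0.02)

    def test_target_below_current_rejected(self, material_set):
        model = RVEModel(empty_rve(), material_set, element_size=0.5)
        st = initial_state(model)
        newton_solve(st, 1.02, substeps=1)
        with pytest.raises(ConfigurationError):
            newton_solve(st, 1.01, substeps=1)


@pytest.fixture(scope="module")
def loaded_state(material_set):
    rve = single_axon_rve(1.05)
    model = RVEModel(rve, material_set, element_size=0.5)
    st = initial_state(model)
    from axonrve.kinematics import update_coupling_states

    coupling = update_coupling_states(rve, st.axon_deformed_nodes(), 1.06)
    st.ties = model.update_ties(st.ties, coupling, st.u)
    newton_solve(st, 1.06, substeps=3)
    return st


class TestPostProcessing:
    def test_reference_von_mises_is_zero(self, material_set):
        model = RVEModel(empty_rve(), material_set, element_size=0.5)
        st = initial_state(model)
        assert np.allclose(von_mises_field(st), 0.0, atol=1e-10)

    def test_von_mises_positive_under_tension(self, loaded_state):
        vm = von_mises_field(loaded_state)
        assert vm.shape == (loaded_state.model.mesh.n_elements,)
        assert np.all(vm > 0)

    def test_boundary_reaction_equals_volume_averaged_p33(self, loaded_state):
        s_boundary = homogenized_nominal_stress(loaded_state)
        s_volume = volume_averaged_p33(loaded_state)
        assert s_boundary == pytest.approx(s_volume, rel=0.01)


@pytest.fixture(scope="module")
def single_axon_result(material_set):
    return staged_simulation(single_axon_rve(1.05), material_set,
                             element_size=0.5)


class TestStagedSimulation:

    def test_curve_starts_at_zero_and_increases(self, single_axon_result):
        res = single_axon_result
        assert res.stretches[0] == 1.0
        assert res.stresses[0] == 0.0
        assert np.all(np.diff(res.stresses) > 0)
        assert res.stretches[-1] == pytest.approx(1.25)

    def test_sub_threshold_axon_coupling_schedule(self, single_axon_result):
        counts = [r["coupled_count"] for r in single_axon_result.coupling_records]
        assert counts == [4, 10, 22]

    def test_tortuosity_non_increasing(self, single_axon_result):
        t = single_axon_result.tortuosity
        series = [t[lam][0] for lam in sorted(t)]
        assert all(b <= a + 1e-9 for a, b in zip(series, series[1:]))

    def test_fibers_never_soften_the_response(self, material_set):
        program = LoadProgram(stage_stretches=(1.06,), substeps=3)
        bare = staged_simulation(empty_rve(), material_set, program=program,
                                 element_size=0.5)
        fibered = staged_simulation(single_axon_rve(1.05), material_set,
                                    program=program, element_size=0.5)
        assert fibered.stresses[-1] >= bare.stresses[-1] - 1e-9

    def test_straight_axon_keeps_unit_tortuosity(self, material_set):
        res = staged_simulation(
            single_axon_rve(1.0), material_set,
            program=LoadProgram(stage_stretches=(1.06,), substeps=2),
            element_size=0.5,
        )
        for torts in res.tortuosity.values():
            assert torts[0] == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_across_runs(self, material_set):
        program = LoadProgram(stage_stretches=(1.06,), substeps=2)
        rve = single_axon_rve(1.1)
        a = staged_simulation(rve, material_set, program=program,
                              element_size=0.5)
        b = staged_simulation(rve, material_set, program=program,
                              element_size=0.5)
        assert np.array_equal(a.stresses, b.stresses)

    def test_trace_table_contains_population_mean(self, single_axon_result):
        df = tortuosity_trace(single_axon_result)
        assert {"axon", "applied_stretch", "tortuosity"} <= set(df.columns)
        assert (df["axon"] == "mean").sum() == len(single_axon_result.tortuosity)
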