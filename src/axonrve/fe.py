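"""Total-Lagrangian hyperelastic FE solver for the embedded-axon RVE.

The matrix phase is meshed with a structured grid of 8-node hexahedra
(trilinear, 2x2x2 Gauss quadrature) carrying the nearly incompressible Ogden
law.  Each axon is a chain of 2-node nonlinear truss segments spanning its
50 sub-segment boundary nodes; a truss segment at stretch ``lam_f`` carries
the axial force ``S(lam_f) * pi r^2`` with ``S`` the incompressible uniaxial
Ogden law, referenced to the segment rest length.  Fiber nodes are tied to
the matrix by penalty springs acting between the fiber node and the matrix
displacement interpolated (trilinearly) at the node's *reference* location:
stiff springs for coupled nodes and the two always-tied end nodes, and a very
soft regularization spring for uncoupled nodes that would otherwise float
transversely.  The matrix volume is not reduced where fibers run, matching
the embedded-element premise.

Loading is staged uniaxial tension along z: ``U_z = 0`` on the ``Z = 0``
face, a prescribed ``U_z`` on the opposite face, lateral faces traction
free, with in-plane rigid-body modes pinned at two corner nodes of the
``Z = 0`` face.  Between stages, per-axon undulation is recomputed from the
deformed fiber nodes and the transitional kinematic model reassigns the
coupled sub-segments; penalty stiffnesses are rebuilt accordingly.

Units: lengths in um, stresses in kPa, forces in kPa*um^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .constitutive import (
    OgdenMaterial,
    pk2_stress,
    pk2_tangent,
    uniaxial_nominal_stress,
    uniaxial_stress_derivative,
)
from .errors import (
    ConfigurationError,
    ConvergenceError,
    ElementInversionError,
    InvalidGeometryError,
)
from .geometry import BoxDomain, RVEGeometry, compute_tortuosity
from .kinematics import CouplingRule, CouplingState, update_coupling_states

logger = logging.getLogger(__name__)

__all__ = [
    "Mesh",
    "MaterialSet",
    "LoadProgram",
    "FEState",
    "HomogenizedResult",
    "SolverOptions",
    "RVEModel",
    "mesh_box",
    "locate_host_and_weights",
    "staged_simulation",
    "homogenized_nominal_stress",
    "von_mises_field",
    "volume_averaged_p33",
    "tortuosity_trace",
]

# local node sign pattern of the trilinear hexahedron
_HEX_SIGNS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
_GAUSS = np.array(
    [[sx / np.sqrt(3.0), sy / np.sqrt(3.0), sz / np.sqrt(3.0)]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)


def _shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at local coordinates xi in [-1, 1]^3."""
    return np.prod(1.0 + _HEX_SIGNS * xi, axis=1) / 8.0


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi_d, shape (8, 3)."""
    g = np.empty((8, 3))
    for d in range(3):
        terms = 1.0 + _HEX_SIGNS * xi
        terms[:, d] = _HEX_SIGNS[:, d]
        g[:, d] = np.prod(terms, axis=1) / 8.0
    return g


@dataclass(frozen=True)
class Mesh:
    """Structured hexahedral grid covering a :class:`BoxDomain` exactly."""

    domain: BoxDomain
    counts: tuple[int, int, int]          # elements per axis
    nodes: np.ndarray                     # (n_nodes, 3) lexicographic (x fastest)
    connectivity: np.ndarray              # (n_elements, 8)
    z0_nodes: np.ndarray
    z1_nodes: np.ndarray

    @property
    def spacing(self) -> np.ndarray:
        return self.domain.sizes / np.asarray(self.counts)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.connectivity)


def mesh_box(domain: BoxDomain, target_element_size: float) -> Mesh:
    """Structured hex mesh with per-axis counts ``max(1, round(size/target))``."""
    if target_element_size <= 0:
        raise ConfigurationError("target element size must be positive")
    counts = tuple(
        max(1, int(np.floor(s / target_element_size + 0.5))) for s in domain.sizes
    )
    nx, ny, nz = counts
    xs = np.linspace(0.0, domain.size_x, nx + 1)
    ys = np.linspace(0.0, domain.size_y, ny + 1)
    zs = np.linspace(0.0, domain.size_z, nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(ix, iy, iz):
        return ix + (nx + 1) * (iy + (ny + 1) * iz)

    # element e = ix + nx*(iy + ny*iz), x fastest -- must match the index
    # arithmetic in locate_host_and_weights
    iz, iy, ix = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    conn = np.column_stack([
        nid(ix, iy, iz), nid(ix + 1, iy, iz), nid(ix + 1, iy + 1, iz),
        nid(ix, iy + 1, iz), nid(ix, iy, iz + 1), nid(ix + 1, iy, iz + 1),
        nid(ix + 1, iy + 1, iz + 1), nid(ix, iy + 1, iz + 1),
    ])
    all_ids = np.arange(len(nodes))
    z0 = all_ids[np.isclose(nodes[:, 2], 0.0)]
    z1 = all_ids[np.isclose(nodes[:, 2], domain.size_z)]
    return Mesh(domain=domain, counts=counts, nodes=nodes, connectivity=conn,
                z0_nodes=z0, z1_nodes=z1)


def locate_host_and_weights(point, mesh: Mesh):
    """Host element and trilinear weights of a point inside the mesh.

    Returns ``(element_id, node_ids (8,), weights (8,))``.  The weights are
    a partition of unity; points exactly on element faces are assigned to
    the lower-index element.
    """
    p = np.asarray(point, dtype=float)
    sizes = mesh.domain.sizes
    if np.any(p < -1e-9) or np.any(p > sizes + 1e-9):
        raise InvalidGeometryError(f"point {p} lies outside the mesh domain")
    h = mesh.spacing
    idx = np.minimum(np.asarray(mesh.counts) - 1,
                     np.maximum(0, np.floor(p / h).astype(int)))
    nx, ny, nz = mesh.counts
    eid = int(idx[0] + nx * (idx[1] + ny * idx[2]))
    xi = 2.0 * (p - idx * h) / h - 1.0
    xi = np.clip(xi, -1.0, 1.0)
    node_ids = mesh.connectivity[eid]
    return eid, node_ids, _shape_functions(xi)


@dataclass
class TieSet:
    """Penalty-tie configuration of all fiber nodes (embedded-element ties)."""

    host_nodes: np.ndarray    # (M, 8) matrix node ids per fiber node
    weights: np.ndarray       # (M, 8) trilinear interpolation weights
    offsets: np.ndarray       # (M, 3) anchor offsets X* - X_f0
    k: np.ndarray             # (M,) spring stiffness, kPa*um
    K: sp.csr_matrix          # constant stiffness operator
    b: np.ndarray             # constant load vector from the offsets


@dataclass(frozen=True)
class MaterialSet:
    """Material pair for the two phases."""

    axon: OgdenMaterial
    ecm: OgdenMaterial

    @classmethod
    def from_axon_modulus(cls, mu_axon: float, alpha: float,
                          mu_ratio_axon_to_ecm: float = 3.0,
                          bulk_penalty_factor: float = 100.0) -> "MaterialSet":
        """Build the pair from the axon modulus and the stiffness ratio.

        The axon phase is ``mu_ratio_axon_to_ecm`` times stiffer than the
        extracellular matrix (default 3x); both share the same exponent.
        """
        mu_ecm = mu_axon / mu_ratio_axon_to_ecm
        return cls(
            axon=OgdenMaterial(mu_axon, alpha, bulk_penalty_factor * mu_axon),
            ecm=OgdenMaterial(mu_ecm, alpha, bulk_penalty_factor * mu_ecm),
        )


@dataclass(frozen=True)
class LoadProgram:
    """Staged uniaxial tension protocol along z."""

    stage_stretches: tuple[float, ...] = (1.06, 1.12, 1.25)
    substeps: int = 6

    def __post_init__(self):
        st = np.asarray(self.stage_stretches)
        if np.any(st <= 1.0) or np.any(np.diff(st) <= 0):
            raise ConfigurationError(
                "stage stretches must be > 1 and strictly increasing"
            )
        if self.substeps < 1:
            raise ConfigurationError("substeps must be >= 1")


@dataclass
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    max_iterations: int = 25
    max_bisections: int = 4
    tie_factor_high: float = 1e3     # k_high = factor * mu_ecm * h
    tie_factor_low: float = 1e-3     # numerical stabilization of floating nodes


class RVEModel:
    """Assembled FE model of one RVE: mesh, fibers, ties, and BCs."""

    def __init__(
        self,
        rve: RVEGeometry,
        materials: MaterialSet,
        element_size: float = 0.4,
        rule: CouplingRule = CouplingRule(),
        options: SolverOptions | None = None,
        selection_policy: str = "straightest",
        seed: int = 0,
        anchor_mode: str = "current",
    ):
        if anchor_mode not in ("current", "reference"):
            raise ConfigurationError(f"unknown anchor_mode {anchor_mode!r}")
        self.rve = rve
        self.materials = materials
        self.rule = rule
        self.options = options or SolverOptions()
        self.selection_policy = selection_policy
        self.seed = seed
        self.anchor_mode = anchor_mode
        self.mesh = mesh_box(rve.domain, element_size)
        self._setup_hex_precomputations()
        self._setup_fibers()
        self._setup_bcs()

    # ----- setup -------------------------------------------------------

    def _setup_hex_precomputations(self):
        mesh = self.mesh
        h = mesh.spacing
        grad = np.empty((8, 8, 3))  # (gauss, node, dim), reference coordinates
        for g, xi in enumerate(_GAUSS):
            grad[g] = _shape_gradients(xi) * (2.0 / h)
        self._gradN = grad
        self._wdet = float(np.prod(h)) / 8.0
        conn = mesh.connectivity
        edof = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 24)
        self._edof = edof
        self._hex_rows = np.repeat(edof, 24, axis=1).ravel()
        self._hex_cols = np.tile(edof, (1, 24)).ravel()

    def _setup_fibers(self):
        mesh = self.mesh
        n_mat_dof = 3 * mesh.n_nodes
        fiber_nodes, seg_pairs, seg_area, seg_axon = [], [], [], []
        self._axon_node_slices = []
        self._axon_seg_slices = []
        offset = 0
        for ai, path in enumerate(self.rve.axons):
            nodes = path.subsegment_nodes
            m = len(nodes)
            fiber_nodes.append(nodes)
            self._axon_node_slices.append(slice(offset, offset + m))
            self._axon_seg_slices.append(
                slice(len(seg_pairs), len(seg_pairs) + m - 1)
            )
            for k in range(m - 1):
                seg_pairs.append((offset + k, offset + k + 1))
                seg_area.append(np.pi * path.radius**2)
                seg_axon.append(ai)
            offset += m
        self.fiber_ref = (
            np.vstack(fiber_nodes) if fiber_nodes else np.zeros((0, 3))
        )
        self.n_fiber_nodes = len(self.fiber_ref)
        self.seg_pairs = np.asarray(seg_pairs, dtype=int).reshape(-1, 2)
        self.seg_area = np.asarray(seg_area)
        self.seg_axon = np.asarray(seg_axon, dtype=int)
        d = np.diff(self.fiber_ref[self.seg_pairs], axis=1)[:, 0, :] \
            if len(self.seg_pairs) else np.zeros((0, 3))
        self.seg_rest_vec = d
        self.seg_rest_len = np.linalg.norm(d, axis=1)
        if np.any(self.seg_rest_len <= 0):
            raise InvalidGeometryError("degenerate fiber segment of zero length")
        self.n_dof = n_mat_dof + 3 * self.n_fiber_nodes
        self._n_mat_dof = n_mat_dof

        # embedding data: host-node ids and trilinear weights per fiber node
        host_nodes = np.empty((self.n_fiber_nodes, 8), dtype=int)
        weights = np.empty((self.n_fiber_nodes, 8))
        for j, p in enumerate(self.fiber_ref):
            _, nid, w = locate_host_and_weights(p, mesh)
            host_nodes[j], weights[j] = nid, w
        self.tie_host_nodes = host_nodes
        self.tie_weights = weights

        # per-axon end-node flags (always tied stiffly)
        self._end_node_mask = np.zeros(self.n_fiber_nodes, dtype=bool)
        for sl in self._axon_node_slices:
            self._end_node_mask[sl.start] = True
            self._end_node_mask[sl.stop - 1] = True

        # precompute the tie pattern: per fiber node, 9 dofs per component
        # (the fiber dof itself plus the 8 host-node dofs)
        jdofs = n_mat_dof + 3 * np.arange(self.n_fiber_nodes)[:, None] \
            + np.arange(3)[None, :]
        self._tie_fiber_dofs = jdofs  # (M, 3)

    def _setup_bcs(self):
        mesh = self.mesh
        self._z1_zdofs = 3 * mesh.z1_nodes + 2
        self._z0_zdofs = 3 * mesh.z0_nodes + 2
        # pin in-plane rigid modes: node nearest (0,0,0) holds ux, uy;
        # node nearest (0, Ly, 0) holds ux (kills rotation about z)
        n_origin = int(np.argmin(np.linalg.norm(mesh.nodes, axis=1)))
        corner = np.array([0.0, mesh.domain.size_y, 0.0])
        n_corner = int(np.argmin(np.linalg.norm(mesh.nodes - corner, axis=1)))
        self._pin_dofs = np.array(
            [3 * n_origin, 3 * n_origin + 1, 3 * n_corner], dtype=int
        )
        presc = np.zeros(self.n_dof, dtype=bool)
        presc[self._z0_zdofs] = True
        presc[self._z1_zdofs] = True
        presc[self._pin_dofs] = True
        self.prescribed_mask = presc
        self.free_mask = ~presc

    # ----- coupling ties ------------------------------------------------

    def tie_stiffnesses(self, coupling: CouplingState | None) -> np.ndarray:
        """Penalty stiffness per fiber node (kPa*um) for a coupling state."""
        h = float(np.prod(self.mesh.spacing) ** (1.0 / 3.0))
        mu = self.materials.ecm.mu
        k_high = self.options.tie_factor_high * mu * h
        k_low = self.options.tie_factor_low * mu * h
        k = np.full(self.n_fiber_nodes, k_low)
        k[self._end_node_mask] = k_high
        if coupling is not None:
            for ai, coupled in enumerate(coupling.coupled_sets):
                sl = self._axon_node_slices[ai]
                for seg in coupled:
                    # a coupled sub-segment ties both of its boundary nodes
                    k[sl.start + seg] = k_high
                    k[sl.start + seg + 1] = k_high
        return k

    def _tie_assemble(self, host_nodes, weights, offsets, k) -> "TieSet":
        """Build the sparse penalty operator for a tie configuration.

        Each fiber node j stores the constraint c_j = u_f,j - N_j u_m - g_j
        with trilinear weights N_j at its anchor point and offset
        g_j = X*_j - X_f0,j (zero for reference-anchored ties); the penalty
        energy is k_j/2 |c_j|^2, giving a constant stiffness K and a load
        vector b = B^T k g.
        """
        M = self.n_fiber_nodes
        if M == 0:
            empty = sp.csr_matrix((self.n_dof, self.n_dof))
            return TieSet(host_nodes=np.zeros((0, 8), dtype=int),
                          weights=np.zeros((0, 8)), offsets=np.zeros((0, 3)),
                          k=np.zeros(0), K=empty, b=np.zeros(self.n_dof))
        coeff = np.concatenate([np.ones((M, 1)), -weights], axis=1)  # (M, 9)
        rows, cols, vals = [], [], []
        b = np.zeros(self.n_dof)
        for c in range(3):
            dofs = np.concatenate(
                [self._tie_fiber_dofs[:, c:c + 1], 3 * host_nodes + c], axis=1
            )  # (M, 9)
            r = np.repeat(dofs, 9, axis=1).ravel()
            cl = np.tile(dofs, (1, 9)).ravel()
            v = (k[:, None, None] * coeff[:, :, None] * coeff[:, None, :]).ravel()
            rows.append(r)
            cols.append(cl)
            vals.append(v)
            np.add.at(b, dofs, (k * offsets[:, c])[:, None] * coeff)
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        )
        return TieSet(host_nodes=host_nodes, weights=weights, offsets=offsets,
                      k=k, K=K.tocsr(), b=b)

    def initial_ties(self) -> "TieSet":
        """Reference-anchored ties: end nodes stiff, interior nodes soft."""
        return self._tie_assemble(
            self.tie_host_nodes.copy(), self.tie_weights.copy(),
            np.zeros((self.n_fiber_nodes, 3)), self.tie_stiffnesses(None),
        )

    def _anchor_point(self, x_f: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Matrix material point X* currently coincident with position x_f.

        Solved by fixed-point iteration of X = x_f - u_m(X), clipped to the
        domain (a fiber node may drift slightly outside the lateral faces).
        """
        u_mat = u[: self._n_mat_dof].reshape(-1, 3)
        sizes = self.mesh.domain.sizes
        X = np.clip(x_f, 0.0, sizes)
        for _ in range(8):
            _, nid, w = locate_host_and_weights(X, self.mesh)
            X_new = np.clip(x_f - w @ u_mat[nid], 0.0, sizes)
            if np.linalg.norm(X_new - X) < 1e-12:
                X = X_new
                break
            X = X_new
        return X

    def update_ties(self, ties: "TieSet", coupling: CouplingState | None,
                    u: np.ndarray) -> "TieSet":
        """Re-evaluate tie stiffnesses for a coupling state.

        A node whose spring switches from the soft to the stiff value is
        re-anchored at the matrix material point currently coincident with
        it, so coupling grabs the fiber where it is rather than dragging it
        back to the (affinely convected) image of its reference position.
        Nodes already stiff keep their anchors.
        """
        k_new = self.tie_stiffnesses(coupling)
        host = ties.host_nodes.copy()
        weights = ties.weights.copy()
        offsets = ties.offsets.copy()
        pos = self.fiber_positions(u)
        switched = np.where(k_new > ties.k * (1.0 + 1e-9))[0]
        if self.anchor_mode == "reference":
            switched = switched[:0]  # keep reference anchors everywhere
        for j in switched:
            X_star = self._anchor_point(pos[j], u)
            _, nid, w = locate_host_and_weights(X_star, self.mesh)
            host[j], weights[j] = nid, w
            offsets[j] = X_star - self.fiber_ref[j]
        return self._tie_assemble(host, weights, offsets, k_new)

    # ----- assembly -----------------------------------------------------

    def _hex_fields(self, u: np.ndarray):
        u_mat = u[: self._n_mat_dof].reshape(-1, 3)
        u_e = u_mat[self.mesh.connectivity]  # (ne, 8, 3)
        F = np.einsum("eai,gaJ->egiJ", u_e, self._gradN, optimize=True)
        F += np.eye(3)
        C = np.einsum("egkI,egkJ->egIJ", F, F, optimize=True)
        return F, C

    def _assemble_hex(self, u: np.ndarray, with_tangent: bool):
        F, C = self._hex_fields(u)
        eids = np.arange(self.mesh.n_elements)
        S = pk2_stress(C, self.materials.ecm, element_ids=eids)
        P = np.einsum("egiI,egIJ->egiJ", F, S, optimize=True)
        f_e = self._wdet * np.einsum("egiJ,gaJ->eai", P, self._gradN, optimize=True)
        r = np.zeros(self.n_dof)
        np.add.at(r, self._edof.reshape(-1, 8, 3), f_e)
        if not with_tangent:
            return r, None
        D2 = 2.0 * pk2_tangent(C, self.materials.ecm)
        T1 = np.einsum("egIJKL,egkK->egIJkL", D2, F, optimize=True)
        T2 = np.einsum("egIJkL,gbL->egIJkb", T1, self._gradN, optimize=True)
        T3 = np.einsum("egiI,egIJkb->egiJkb", F, T2, optimize=True)
        K_mat = self._wdet * np.einsum("gaJ,egiJkb->eaibk", self._gradN, T3, optimize=True)
        G = self._wdet * np.einsum("gaJ,egJL,gbL->eab", self._gradN, S, self._gradN, optimize=True)
        K_e = K_mat + np.einsum("eab,ik->eaibk", G, np.eye(3))
        K_e = K_e.reshape(-1, 24, 24)
        K_e = 0.5 * (K_e + K_e.transpose(0, 2, 1))
        K = sp.coo_matrix(
            (K_e.ravel(), (self._hex_rows, self._hex_cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        return r, K

    def fiber_positions(self, u: np.ndarray) -> np.ndarray:
        return self.fiber_ref + u[self._n_mat_dof:].reshape(-1, 3)

    def _assemble_trusses(self, u: np.ndarray, with_tangent: bool):
        r = np.zeros(self.n_dof)
        if len(self.seg_pairs) == 0:
            return r, (sp.csr_matrix((self.n_dof, self.n_dof))
                       if with_tangent else None)
        pos = self.fiber_positions(u)
        x1 = pos[self.seg_pairs[:, 0]]
        x2 = pos[self.seg_pairs[:, 1]]
        dv = x2 - x1
        l = np.linalg.norm(dv, axis=1)
        if np.any(l < 1e-12):
            raise ElementInversionError(
                "fiber segment collapsed to zero length",
                element_ids=np.where(l < 1e-12)[0],
            )
        d = dv / l[:, None]
        lam = l / self.seg_rest_len
        mats = self.materials.axon
        Nf = uniaxial_nominal_stress(lam, mats) * self.seg_area
        dof1 = self._tie_fiber_dofs[self.seg_pairs[:, 0]]
        dof2 = self._tie_fiber_dofs[self.seg_pairs[:, 1]]
        np.add.at(r, dof1, -Nf[:, None] * d)
        np.add.at(r, dof2, Nf[:, None] * d)
        if not with_tangent:
            return r, None
        dN = uniaxial_stress_derivative(lam, mats) * self.seg_area
        eye = np.eye(3)
        ddT = np.einsum("si,sj->sij", d, d)
        k_blk = (dN / self.seg_rest_len)[:, None, None] * ddT \
            + (Nf / l)[:, None, None] * (eye - ddT)
        ns = len(self.seg_pairs)
        K_e = np.empty((ns, 6, 6))
        K_e[:, :3, :3] = k_blk
        K_e[:, 3:, 3:] = k_blk
        K_e[:, :3, 3:] = -k_blk
        K_e[:, 3:, :3] = -k_blk
        edof = np.concatenate([dof1, dof2], axis=1)  # (ns, 6)
        rows = np.repeat(edof, 6, axis=1).ravel()
        cols = np.tile(edof, (1, 6)).ravel()
        K = sp.coo_matrix(
            (K_e.ravel(), (rows, cols)), shape=(self.n_dof, self.n_dof)
        ).tocsr()
        return r, K

    def assemble(self, u: np.ndarray, ties: "TieSet",
                 with_tangent: bool = True):
        """Residual (internal forces) and consistent tangent at state ``u``."""
        r_hex, K_hex = self._assemble_hex(u, with_tangent)
        r_tr, K_tr = self._assemble_trusses(u, with_tangent)
        r = r_hex + r_tr + ties.K @ u - ties.b
        if not with_tangent:
            return r, None
        return r, K_hex + K_tr + ties.K

    def tie_targets(self, u: np.ndarray, ties: "TieSet") -> np.ndarray:
        """Displacement target of every fiber node's penalty spring: the
        interpolated matrix displacement at its anchor plus the anchor
        offset, shape (n_fiber_nodes, 3)."""
        u_mat = u[: self._n_mat_dof].reshape(-1, 3)
        return np.einsum("ja,jak->jk", ties.weights,
                         u_mat[ties.host_nodes]) + ties.offsets

    def relax_chains(self, u: np.ndarray, ties: "TieSet",
                     rtol: float = 1e-10, max_iter: int = 60) -> np.ndarray:
        """Equilibrate each fiber chain with the matrix field frozen.

        Uncoupled chains are transversely floppy (their only transverse
        stiffness is the soft regularization spring), which makes the global
        Newton iteration bounce through large rotations.  Solving each
        axon's small dense chain problem first (damped Newton with an energy
        line search) removes those soft modes from the global solve at
        negligible cost.  The global residual check is unaffected: the
        relaxed state is simply a much better iterate.
        """
        if self.n_fiber_nodes == 0:
            return u
        u = u.copy()
        targets = self.tie_targets(u, ties)
        mats = self.materials.axon
        a = mats.alpha

        def chain_energy(q, X, k, t, L0, A):
            dv = np.diff(X + q, axis=0)
            l = np.linalg.norm(dv, axis=1)
            lam = l / L0
            W = (2.0 * mats.mu / a**2) * (lam**a + 2.0 * lam ** (-a / 2.0) - 3.0)
            return float(np.sum(W * A * L0) + 0.5 * np.sum(k * ((q - t) ** 2).sum(1)))

        # only soft (uncoupled) nodes are relaxed here; stiffly tied nodes
        # are strongly coupled to the matrix and are left to the global
        # Newton solve, otherwise the alternation cycles
        h_mesh = float(np.prod(self.mesh.spacing) ** (1.0 / 3.0))
        k_threshold = self.materials.ecm.mu * h_mesh  # geometric mean of hi/lo
        for sl_n, sl_s in zip(self._axon_node_slices, self._axon_seg_slices):
            X = self.fiber_ref[sl_n]
            m = len(X)
            d0 = self._n_mat_dof + 3 * sl_n.start
            d1 = self._n_mat_dof + 3 * sl_n.stop
            q = u[d0:d1].reshape(m, 3)
            k = ties.k[sl_n]
            t = targets[sl_n]
            soft = k < k_threshold
            if not soft.any():
                continue
            fdof = np.flatnonzero(np.repeat(soft, 3))
            L0 = self.seg_rest_len[sl_s]
            A = self.seg_area[sl_s]
            E = chain_energy(q, X, k, t, L0, A)
            for _ in range(max_iter):
                x = X + q
                dv = np.diff(x, axis=0)
                l = np.linalg.norm(dv, axis=1)
                lam = l / L0
                d = dv / l[:, None]
                Nf = uniaxial_nominal_stress(lam, mats) * A
                r = np.zeros((m, 3))
                np.subtract.at(r, np.arange(m - 1), Nf[:, None] * d)
                np.add.at(r, np.arange(1, m), Nf[:, None] * d)
                r += k[:, None] * (q - t)
                rn = float(np.linalg.norm(r.ravel()[fdof]))
                if rn <= max(1e-12, rtol * max(1.0, float(np.abs(Nf).max(initial=0.0)))):
                    break
                dN = uniaxial_stress_derivative(lam, mats) * A
                ddT = np.einsum("si,sj->sij", d, d)
                kb = (dN / L0)[:, None, None] * ddT \
                    + (Nf / l)[:, None, None] * (np.eye(3) - ddT)
                K = np.zeros((m, 3, m, 3))
                idx = np.arange(m - 1)
                K[idx, :, idx, :] += kb
                K[idx + 1, :, idx + 1, :] += kb
                K[idx, :, idx + 1, :] -= kb
                K[idx + 1, :, idx, :] -= kb
                K = K.reshape(3 * m, 3 * m)
                K[np.arange(3 * m), np.arange(3 * m)] += np.repeat(k, 3)
                dq = np.zeros(3 * m)
                try:
                    dq[fdof] = np.linalg.solve(
                        K[np.ix_(fdof, fdof)], -r.ravel()[fdof]
                    )
                except np.linalg.LinAlgError:
                    dq[fdof] = -(r.ravel() / np.repeat(np.maximum(k, 1e-12), 3))[fdof]
                dq = dq.reshape(m, 3)
                s = 1.0
                improved = False
                for _ in range(12):
                    q_try = q + s * dq
                    l_try = np.linalg.norm(np.diff(X + q_try, axis=0), axis=1)
                    if np.all(l_try > 0.01 * L0):
                        E_try = chain_energy(q_try, X, k, t, L0, A)
                        if E_try <= E + 1e-12 * max(1.0, abs(E)):
                            q, E, improved = q_try, E_try, True
                            break
                    s *= 0.5
                if not improved:
                    break
            u[d0:d1] = q.ravel()
        return u

    # ----- boundary conditions -----------------------------------------

    def prescribed_values(self, applied_stretch: float) -> np.ndarray:
        vals = np.zeros(self.n_dof)
        vals[self._z1_zdofs] = (applied_stretch - 1.0) * self.mesh.domain.size_z
        return vals


@dataclass
class FEState:
    """Displacement state of the model at one accepted load level."""

    model: RVEModel
    u: np.ndarray
    applied_stretch: float = 1.0
    coupling: CouplingState | None = None
    ties: "TieSet | None" = None
    last_residual: np.ndarray | None = None
    newton_iterations: int = 0

    @property
    def fiber_positions(self) -> np.ndarray:
        return self.model.fiber_positions(self.u)

    def axon_deformed_nodes(self) -> list[np.ndarray]:
        pos = self.fiber_positions
        return [pos[sl] for sl in self.model._axon_node_slices]

    def deformation_gradients(self) -> np.ndarray:
        """Per-element, per-Gauss-point deformation gradients (ne, 8, 3, 3)."""
        return self.model._hex_fields(self.u)[0]


def initial_state(model: RVEModel) -> FEState:
    st = FEState(model=model, u=np.zeros(model.n_dof))
    st.ties = model.initial_ties()
    st.last_residual = np.zeros(model.n_dof)
    return st


def _newton_increment(model: RVEModel, state: FEState, lam: float) -> None:
    """Solve one displacement-controlled increment to applied stretch lam."""
    opts = model.options
    u = state.u.copy()
    # predictor: carry the stretch increment as a linear axial ramp so the
    # first iterate is not concentrated in the top element layer
    dlam = lam - state.applied_stretch
    if abs(dlam) > 0:
        z_ref = np.concatenate([model.mesh.nodes[:, 2], model.fiber_ref[:, 2]]) \
            if model.n_fiber_nodes else model.mesh.nodes[:, 2]
        u[2::3] += dlam * z_ref
    u[model.prescribed_mask] = model.prescribed_values(lam)[model.prescribed_mask]
    if model.n_fiber_nodes:
        u = model.relax_chains(u, state.ties)
    free = model.free_mask
    step_cap = 0.5 * float(model.mesh.spacing.min())
    for it in range(opts.max_iterations + 1):
        try:
            r, K = model.assemble(u, state.ties, with_tangent=True)
        except ElementInversionError:
            raise ConvergenceError(
                f"iterate at stretch {lam:.5f} reached a near-inverted "
                "element state", applied_stretch=lam, iterations=it,
            )
        rn = float(np.linalg.norm(r[free]))
        ref = float(np.linalg.norm(r))
        if rn <= max(opts.atol, opts.rtol * max(ref, 1.0)):
            state.u = u
            state.applied_stretch = lam
            state.last_residual = r
            state.newton_iterations = it
            logger.debug("lambda=%.5f converged in %d iterations (|r|=%.3e)",
                         lam, it, rn)
            return
        if it == opts.max_iterations:
            raise ConvergenceError(
                f"Newton did not converge at stretch {lam:.5f} "
                f"({it} iterations, |r| = {rn:.3e})",
                applied_stretch=lam, iterations=it, residual_norm=rn,
            )
        Kff = K[free][:, free].tocsc()
        du = splu(Kff, permc_spec="MMD_ATA").solve(-r[free])
        # trust-region-style cap keeps stiff tie switches from overshooting
        du_max = float(np.abs(du).max())
        if du_max > step_cap:
            du *= step_cap / du_max
        # backtracking: accept the first feasible scale that reduces the
        # residual; failing that, the smallest feasible (damped) step
        accepted, fallback = None, None
        scale = 1.0
        for _ in range(7):
            u_try = u.copy()
            u_try[free] += scale * du
            try:
                r_try, _ = model.assemble(u_try, state.ties,
                                          with_tangent=False)
            except ElementInversionError:
                scale *= 0.5
                continue
            if fallback is None:
                fallback = u_try
            if float(np.linalg.norm(r_try[free])) < rn:
                accepted = u_try
                break
            scale *= 0.5
        if accepted is None and fallback is None:
            raise ElementInversionError(
                "no feasible Newton step found", applied_stretch=lam
            )
        u = accepted if accepted is not None else fallback
        if model.n_fiber_nodes:
            u = model.relax_chains(u, state.ties)


def newton_solve(state: FEState, target_stretch: float, substeps: int) -> FEState:
    """March the state to ``target_stretch`` in equal stretch increments.

    If an increment fails to converge it is bisected (up to
    ``SolverOptions.max_bisections`` times) before the failure is raised.
    Returns the same state object, updated in place.
    """
    model = state.model
    if target_stretch < state.applied_stretch - 1e-12:
        raise ConfigurationError("target stretch must not be below current")
    if abs(target_stretch - state.applied_stretch) < 1e-14:
        return state
    levels = np.linspace(state.applied_stretch, target_stretch, substeps + 1)[1:]
    for lam in levels:
        _solve_with_bisection(model, state, state.applied_stretch, lam, 0)
    return state


def _solve_with_bisection(model, state, lam_from, lam_to, depth):
    try:
        _newton_increment(model, state, lam_to)
    except (ConvergenceError, ElementInversionError):
        if depth >= model.options.max_bisections:
            raise
        mid = 0.5 * (lam_from + lam_to)
        _solve_with_bisection(model, state, lam_from, mid, depth + 1)
        _solve_with_bisection(model, state, mid, lam_to, depth + 1)


def _equilibrate_ties(model, state, ties_old, ties_new):
    """Re-equilibrate at constant stretch after a coupling update.

    Switching a penalty spring from the soft regularization value to the
    stiff coupled value mid-protocol introduces a large force misfit at the
    newly coupled fiber nodes.  The switch is applied as a continuation in
    the tie stiffness (halving the step on failure) so Newton always starts
    from a nearby equilibrium; the final state is the equilibrium under the
    fully switched ties and does not depend on the continuation path.
    """

    def attempt(f_lo, f_hi, depth):
        if f_hi >= 1.0:
            state.ties = ties_new
        else:
            k = ties_old.k + f_hi * (ties_new.k - ties_old.k)
            state.ties = model._tie_assemble(
                ties_new.host_nodes, ties_new.weights, ties_new.offsets, k
            )
        try:
            _newton_increment(model, state, state.applied_stretch)
        except (ConvergenceError, ElementInversionError):
            if depth >= model.options.max_bisections + 2:
                raise
            mid = 0.5 * (f_lo + f_hi)
            attempt(f_lo, mid, depth + 1)
            attempt(mid, f_hi, depth + 1)

    attempt(0.0, 1.0, 0)


# ----- post-processing --------------------------------------------------


def homogenized_nominal_stress(state: FEState) -> float:
    """Nominal stress S33 (kPa): z-reactions on the top face over its area."""
    r = state.last_residual
    if r is None:
        r, _ = state.model.assemble(state.u, state.ties, with_tangent=False)
    reaction = float(r[state.model._z1_zdofs].sum())
    dom = state.model.mesh.domain
    return reaction / (dom.size_x * dom.size_y)


def _cauchy_per_element(state: FEState) -> np.ndarray:
    F, C = state.model._hex_fields(state.u)
    S = pk2_stress(C, state.model.materials.ecm)
    J = np.linalg.det(F)
    sigma = np.einsum("egiI,egIJ,egjJ->egij", F, S, F, optimize=True) / J[..., None, None]
    return sigma.mean(axis=1)  # element average over Gauss points


def von_mises_field(state: FEState) -> np.ndarray:
    """Von Mises invariant of the element-averaged Cauchy stress (kPa)."""
    sig = _cauchy_per_element(state)
    dev = sig - np.trace(sig, axis1=1, axis2=2)[:, None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))


def volume_averaged_p33(state: FEState) -> float:
    """Volume average of the first Piola-Kirchhoff component P33 (kPa).

    Includes the fiber contribution (current axial force times reference
    segment vector).  At equilibrium this equals the boundary-reaction
    measure of :func:`homogenized_nominal_stress`.
    """
    model = state.model
    F, C = model._hex_fields(state.u)
    S = pk2_stress(C, model.materials.ecm)
    P = np.einsum("egiI,egIJ->egiJ", F, S, optimize=True)
    total = model._wdet * P[..., 2, 2].sum()
    if len(model.seg_pairs):
        pos = model.fiber_positions(state.u)
        dv = pos[model.seg_pairs[:, 1]] - pos[model.seg_pairs[:, 0]]
        l = np.linalg.norm(dv, axis=1)
        lam = l / model.seg_rest_len
        Nf = uniaxial_nominal_stress(lam, model.materials.axon) * model.seg_area
        d = dv / l[:, None]
        total += float(np.sum(Nf * d[:, 2] * model.seg_rest_vec[:, 2]))
    return total / model.mesh.domain.volume


@dataclass
class HomogenizedResult:
    """Staged-simulation output: curve, tortuosity trace, and fields."""

    stretches: np.ndarray                 # curve abscissa, starts at 1.0
    stresses: np.ndarray                  # homogenized S33, kPa
    tortuosity: dict[float, np.ndarray]   # per-axon undulation at stage ends
    coupling_records: tuple[dict, ...]
    von_mises: np.ndarray                 # per-element field at the final state
    final_state: FEState | None = None

    @property
    def curve(self) -> np.ndarray:
        return np.column_stack([self.stretches, self.stresses])


def tortuosity_trace(result: HomogenizedResult):
    """Tidy table (axon id, applied stretch, tortuosity) plus population mean."""
    import pandas as pd

    rows = []
    for lam, torts in sorted(result.tortuosity.items()):
        for i, t in enumerate(torts):
            rows.append({"axon": i, "applied_stretch": lam, "tortuosity": t})
    df = pd.DataFrame(rows)
    if len(df):
        mean = df.groupby("applied_stretch", as_index=False)["tortuosity"].mean()
        mean["axon"] = "mean"
        df = pd.concat([df, mean], ignore_index=True)
    return df


def staged_simulation(
    rve: RVEGeometry,
    materials: MaterialSet,
    program: LoadProgram = LoadProgram(),
    rule: CouplingRule = CouplingRule(),
    element_size: float = 0.4,
    options: SolverOptions | None = None,
    selection_policy: str = "straightest",
    seed: int = 0,
    keep_state: bool = False,
    anchor_mode: str = "current",
) -> HomogenizedResult:
    """Run the staged uniaxial protocol on one RVE.

    Before each stage the transitional kinematic model is re-evaluated at
    the stage's target stretch using the *current deformed* per-axon
    undulation, the penalty ties are rebuilt, and the stage is solved in
    ``program.substeps`` equal stretch increments.  The homogenized nominal
    stress is recorded at every accepted substep, and the per-axon
    tortuosity at the reference state and after every stage.
    """
    model = RVEModel(
        rve, materials, element_size=element_size, rule=rule, options=options,
        selection_policy=selection_policy, seed=seed, anchor_mode=anchor_mode,
    )
    state = initial_state(model)
    lams = [1.0]
    stresses = [0.0]
    tort = {1.0: np.array([compute_tortuosity(n)
                           for n in state.axon_deformed_nodes()])} \
        if rve.n_axons else {1.0: np.empty(0)}
    records: list[dict] = []
    coupling = None
    for stage_lam in program.stage_stretches:
        if rve.n_axons:
            coupling = update_coupling_states(
                rve, state.axon_deformed_nodes(), stage_lam, rule,
                previous=coupling, policy=selection_policy, seed=seed,
            )
            records.extend(coupling.records)
            state.coupling = coupling
            ties_new = model.update_ties(state.ties, coupling, state.u)
            if state.applied_stretch > 1.0 + 1e-12:
                _equilibrate_ties(model, state, state.ties, ties_new)
            else:
                state.ties = ties_new
            logger.info(
                "stage lambda=%.3f: mean undulation %.4f, coupled counts %s",
                stage_lam, float(coupling.tortuosities.mean()),
                coupling.coupled_counts().tolist(),
            )
        lam0 = state.applied_stretch
        levels = np.linspace(lam0, stage_lam, program.substeps + 1)[1:]
        for lam in levels:
            _solve_with_bisection(model, state, state.applied_stretch, lam, 0)
            lams.append(lam)
            stresses.append(homogenized_nominal_stress(state))
        if rve.n_axons:
            tort[stage_lam] = np.array(
                [compute_tortuosity(n) for n in state.axon_deformed_nodes()]
            )
        else:
            tort[stage_lam] = np.empty(0)
    vm = von_mises_field(state)
    return HomogenizedResult(
        stretches=np.array(lams),
        stresses=np.array(stresses),
        tortuosity=tort,
        coupling_records=tuple(records),
        von_mises=vm,
        final_state=state if keep_state else None,
    )
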