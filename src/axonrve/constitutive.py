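"""One-term Ogden hyperelasticity for the axon and extracellular-matrix phases.

The strain energy per unit reference volume is the standard one-term Ogden
form written in principal stretches,

    W_iso = (2 mu / alpha^2) (lam1~^alpha + lam2~^alpha + lam3~^alpha - 3),

where ``mu`` is the small-strain shear modulus (kPa) and ``alpha`` the
dimensionless nonlinearity exponent.  The finite-element solver works with a
nearly incompressible decoupled form: the stretches entering ``W_iso`` are the
isochoric ones, lam_i~ = J^(-1/3) lam_i, and a quadratic volumetric penalty

    W_vol = (kappa / 2) (J - 1)^2

with ``kappa = bulk_penalty`` enforces J ~= 1.  The closed-form uniaxial
nominal stress assumes exact incompressibility,

    S(lam) = (2 mu / alpha) (lam^(alpha-1) - lam^(-alpha/2-1)),

which is the response of a tension specimen that is free to contract
laterally.  Units are kPa for stresses and energies throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ElementInversionError

__all__ = [
    "OgdenMaterial",
    "ogden_energy",
    "uniaxial_nominal_stress",
    "uniaxial_stress_derivative",
    "pk2_stress",
    "pk2_tangent",
    "stress_and_tangent",
]


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden material.

    Parameters
    ----------
    mu : float
        Shear modulus in kPa; must be positive.
    alpha : float
        Nonlinearity exponent; must be nonzero.
    bulk_penalty : float, optional
        Volumetric penalty modulus kappa in kPa, used only by the FE solver.
        Defaults to ``100 * mu`` (approximately Poisson ratio 0.495) and must
        be at least ``10 * mu`` for the nearly incompressible formulation to
        be meaningful.
    """

    mu: float
    alpha: float
    bulk_penalty: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.mu > 0:
            raise ConfigurationError(f"shear modulus must be positive, got {self.mu}")
        if self.alpha == 0:
            raise ConfigurationError("Ogden exponent alpha must be nonzero")
        if self.bulk_penalty is None:
            object.__setattr__(self, "bulk_penalty", 100.0 * self.mu)
        if self.bulk_penalty < 10.0 * self.mu:
            raise ConfigurationError(
                f"bulk_penalty {self.bulk_penalty} kPa is below 10*mu = {10 * self.mu} kPa"
            )


def ogden_energy(stretches, mat: OgdenMaterial) -> float:
    """Strain-energy density (kPa) at the given principal stretches.

    The isochoric part is evaluated on lam_i~ = J^(-1/3) lam_i and the
    volumetric penalty on J = lam1 lam2 lam3, so compressible states are
    admissible.  ``stretches`` is a length-3 sequence (or an (..., 3) array)
    of positive principal stretches.
    """
    lam = np.asarray(stretches, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected three principal stretches")
    if np.any(lam <= 0):
        raise ValueError("principal stretches must be positive")
    J = np.prod(lam, axis=-1)
    lam_bar = lam * J[..., None] ** (-1.0 / 3.0)
    w_iso = (2.0 * mat.mu / mat.alpha**2) * (
        np.sum(lam_bar**mat.alpha, axis=-1) - 3.0
    )
    w_vol = 0.5 * mat.bulk_penalty * (J - 1.0) ** 2
    out = w_iso + w_vol
    return float(out) if out.ndim == 0 else out


def uniaxial_nominal_stress(lam, mat: OgdenMaterial):
    """Closed-form incompressible uniaxial nominal (engineering) stress, kPa.

    ``S(lam) = (2 mu / alpha) (lam^(alpha-1) - lam^(-alpha/2-1))`` is the
    derivative of ``W(lam, lam^-1/2, lam^-1/2)`` with respect to ``lam``.
    Accepts scalars or arrays; ``lam`` must be positive.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    a = mat.alpha
    out = (2.0 * mat.mu / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return float(out) if out.ndim == 0 else out


def uniaxial_stress_derivative(lam, mat: OgdenMaterial):
    """dS/dlam of the incompressible uniaxial law (kPa per unit stretch)."""
    lam = np.asarray(lam, dtype=float)
    a = mat.alpha
    out = (2.0 * mat.mu / a) * (
        (a - 1.0) * lam ** (a - 2.0) + (a / 2.0 + 1.0) * lam ** (-a / 2.0 - 2.0)
    )
    return float(out) if out.ndim == 0 else out


def _principal_pk2(C, mu: float, alpha: float, kappa: float, element_ids=None):
    """Second Piola-Kirchhoff stress from stacked right Cauchy-Green tensors.

    ``C`` has shape (..., 3, 3) and must be symmetric positive definite.
    Returns an array of the same shape.  The stress follows from the spectral
    decomposition C = sum_b lam_b^2 N_b N_b^T:

        tau_b = (2 mu / alpha)(lam_b~^alpha - mean_a lam_a~^alpha)   (isochoric)
              + kappa (J - 1) J                                      (volumetric)
        S     = sum_b (tau_b / lam_b^2) N_b N_b^T.

    S is a smooth isotropic function of C, so the expression is well defined
    even at repeated eigenvalues where the eigenvectors themselves are not.
    """
    w, V = np.linalg.eigh(C)
    # reject outright inversion and absurdly collapsed states (stretch below
    # 1% -- far outside the model's regime) so that trial Newton iterates
    # near the singularity are turned back by the line search
    if np.any(w <= 1e-4):
        bad = np.unique(np.argwhere(np.any(w <= 0.0, axis=-1))[:, 0]) if C.ndim > 2 else None
        if element_ids is not None and bad is not None:
            bad = np.asarray(element_ids)[bad]
        raise ElementInversionError(
            "non-positive-definite right Cauchy-Green tensor (det F <= 0)",
            element_ids=bad,
        )
    lam = np.sqrt(w)
    J = np.prod(lam, axis=-1)
    lam_bar_a = (lam * J[..., None] ** (-1.0 / 3.0)) ** alpha
    tau_iso = (2.0 * mu / alpha) * (lam_bar_a - np.mean(lam_bar_a, axis=-1, keepdims=True))
    tau_vol = (kappa * (J - 1.0) * J)[..., None]
    s_principal = (tau_iso + tau_vol) / w  # tau_b / lam_b^2
    return np.einsum("...ab,...b,...cb->...ac", V, s_principal, V, optimize=True)


def pk2_stress(C, mat: OgdenMaterial, element_ids=None):
    """Second Piola-Kirchhoff stress (kPa) for stacked C tensors (..., 3, 3)."""
    return _principal_pk2(np.asarray(C, dtype=float), mat.mu, mat.alpha,
                          mat.bulk_penalty, element_ids=element_ids)


# Symmetric perturbation directions for the finite-difference tangent: three
# axial and three shear modes of C, in the order xx, yy, zz, yz, xz, xy.
_SYM_BASIS = np.zeros((6, 3, 3))
for _m, (_i, _j) in enumerate([(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]):
    _SYM_BASIS[_m, _i, _j] = 1.0
    _SYM_BASIS[_m, _j, _i] = 1.0


def pk2_tangent(C, mat: OgdenMaterial, rel_step: float = 1e-6):
    """Material tangent dS/dC as a (..., 3, 3, 3, 3) array.

    Computed by central differences of the spectral stress along the six
    symmetric perturbation modes of C.  The step is scaled by tr(C)/3 per
    point, which keeps the truncation and round-off errors both near 1e-9
    relative -- far below the Newton solver's needs.  The returned tensor has
    both minor symmetries by construction and major symmetry to
    finite-difference accuracy.
    """
    C = np.asarray(C, dtype=float)
    h = rel_step * (np.trace(C, axis1=-2, axis2=-1) / 3.0)
    cols = []
    for m in range(6):
        E = _SYM_BASIS[m]
        dC = h[..., None, None] * E
        Sp = _principal_pk2(C + dC, mat.mu, mat.alpha, mat.bulk_penalty)
        Sm = _principal_pk2(C - dC, mat.mu, mat.alpha, mat.bulk_penalty)
        cols.append((Sp - Sm) / (2.0 * h[..., None, None]))
    # cols[m] = directional derivative of S along basis E_m.  Diagonal modes
    # give dS/dC_kk directly; shear modes perturb C_kl and C_lk together, so
    # each single-entry derivative is half the directional one.
    # D_IJKL = dS_IJ / dC_KL.
    out = np.empty(C.shape[:-2] + (3, 3, 3, 3))
    for m, (k, l) in enumerate([(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]):
        if k == l:
            out[..., :, :, k, l] = cols[m]
        else:
            out[..., :, :, k, l] = 0.5 * cols[m]
            out[..., :, :, l, k] = 0.5 * cols[m]
    return out


def stress_and_tangent(F, mat: OgdenMaterial, element_id=None):
    """Cauchy stress and first-elasticity tangent A = dP/dF at one state.

    Parameters
    ----------
    F : (3, 3) array
        Deformation gradient with det F > 0.
    mat : OgdenMaterial

    Returns
    -------
    sigma : (3, 3) array
        Cauchy stress, kPa.
    A : (3, 3, 3, 3) array
        dP_iJ/dF_kL of the first Piola-Kirchhoff stress, consistent with
        ``sigma`` to finite-difference accuracy (central differences).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ElementInversionError(
            f"det F = {J:.3e} <= 0", element_ids=element_id
        )
    C = F.T @ F
    S = pk2_stress(C, mat)
    sigma = (F @ S @ F.T) / J

    def first_pk(Fx):
        return Fx @ pk2_stress(Fx.T @ Fx, mat)

    h = 1e-6 * max(1.0, float(np.abs(F).max()))
    A = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            dF = np.zeros((3, 3))
            dF[k, l] = h
            A[:, :, k, l] = (first_pk(F + dF) - first_pk(F - dF)) / (2.0 * h)
    return sigma, A
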