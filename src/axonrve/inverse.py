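"""Inverse identification of the axon shear modulus.

The unknown is the axon shear modulus ``mu`` (the extracellular matrix is a
fixed factor softer, both phases share the Ogden exponent ``alpha``).  The
objective is the summed squared mismatch between a target and a simulated
nominal stress-stretch curve at ``m`` equidistant stretch sample points,

    E(mu) = sum_i ( S_target(lam_i) - S_sim(lam_i; mu) )^2 ,    [kPa^2]

minimized over a bracket by golden-section search: the bracket shrinks by
the inverse golden ratio per objective evaluation and the iteration stops
when its width falls below the tolerance (default 1.0 kPa).  Objective
evaluations are memoized on ``mu`` so no forward solve is repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, ExtrapolationError
from .fe import HomogenizedResult, LoadProgram, MaterialSet, SolverOptions, staged_simulation
from .geometry import RVEGeometry
from .kinematics import CouplingRule

__all__ = [
    "StressStretchCurve",
    "InverseProblem",
    "SearchTrace",
    "sample_stretch_points",
    "squared_error",
    "golden_section_search",
    "identify_shear_modulus",
    "sensitivity_scan",
    "make_forward",
    "simulated_curve",
]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # 1/phi ~= 0.6180339887


@dataclass(frozen=True)
class StressStretchCurve:
    """Nominal stress (kPa) versus stretch, with a provenance tag."""

    stretches: np.ndarray
    stresses: np.ndarray
    source: str = "synthetic"  # experimental | simulated | synthetic

    def __post_init__(self):
        lam = np.asarray(self.stretches, dtype=float)
        s = np.asarray(self.stresses, dtype=float)
        object.__setattr__(self, "stretches", lam)
        object.__setattr__(self, "stresses", s)
        if lam.shape != s.shape or lam.ndim != 1:
            raise ConfigurationError("stretches and stresses must be equal-length 1D")
        if len(lam) and np.any(np.diff(lam) <= 0):
            raise ConfigurationError("stretches must be strictly increasing")

    def interpolate(self, points) -> np.ndarray:
        """Linear interpolation; querying outside the sampled range raises."""
        pts = np.asarray(points, dtype=float)
        if np.any(pts < self.stretches[0] - 1e-12) or \
           np.any(pts > self.stretches[-1] + 1e-12):
            raise ExtrapolationError(
                f"stretch query outside the curve range "
                f"[{self.stretches[0]:.4f}, {self.stretches[-1]:.4f}]"
            )
        return np.interp(pts, self.stretches, self.stresses)


def simulated_curve(result: HomogenizedResult) -> StressStretchCurve:
    """Wrap a staged-simulation output as a curve tagged ``simulated``."""
    return StressStretchCurve(result.stretches, result.stresses, source="simulated")


def sample_stretch_points(lambda_max: float, m: int = 20) -> np.ndarray:
    """Right endpoints of ``m`` equidistant stretch intervals over (1, lambda_max].

    The trivial zero-stress point at lam = 1 is excluded.
    """
    if lambda_max <= 1.0:
        raise ConfigurationError("lambda_max must exceed 1")
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return 1.0 + np.arange(1, m + 1) * (lambda_max - 1.0) / m


def squared_error(target: StressStretchCurve, simulated: StressStretchCurve,
                  points) -> float:
    """E = sum_i (S_target(lam_i) - S_sim(lam_i))^2 in kPa^2."""
    pts = np.asarray(points, dtype=float)
    diff = target.interpolate(pts) - simulated.interpolate(pts)
    return float(np.sum(diff**2))


@dataclass
class SearchTrace:
    """Ordered objective evaluations of one golden-section run."""

    records: list = field(default_factory=list)  # (iteration, mu, E)
    final_mu: float = np.nan
    final_objective: float = np.nan
    final_interval: float = np.nan

    def log(self, mu: float, value: float):
        self.records.append((len(self.records) + 1, float(mu), float(value)))

    @property
    def n_evaluations(self) -> int:
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["iteration", "mu_kPa", "E_kPa2"])


def golden_section_search(
    objective: Callable[[float], float],
    bracket: tuple[float, float],
    tol: float,
) -> tuple[float, SearchTrace]:
    """Textbook golden-section minimization with a full evaluation trace.

    The two initial interior points sit at ``a + (1 - 1/phi)(b - a)`` and
    ``a + (1/phi)(b - a)`` and are evaluated lower-first; every further
    iteration evaluates exactly one new point.  The bracket containing the
    minimum shrinks by ``1/phi`` per evaluation, so the run terminates after
    ``ceil(log(tol/(b-a)) / log(1/phi)) + 1`` evaluations.  The returned
    minimizer is the evaluated interior point with the smallest objective.
    The objective is assumed unimodal on the bracket; this is not verified.
    """
    a, b = float(bracket[0]), float(bracket[1])
    if tol <= 0:
        raise ConfigurationError("tolerance must be positive")
    if a > b:
        raise ConfigurationError(f"bracket must be ordered, got ({a}, {b})")
    trace = SearchTrace()
    if a == b:
        f = float(objective(a))
        trace.log(a, f)
        trace.final_mu, trace.final_objective, trace.final_interval = a, f, 0.0
        return a, trace

    x1 = a + (1.0 - _INVPHI) * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = float(objective(x1))
    trace.log(x1, f1)
    f2 = float(objective(x2))
    trace.log(x2, f2)
    best_mu, best_f = (x1, f1) if f1 <= f2 else (x2, f2)
    while True:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = None
        else:
            a, x1, f1 = x1, x2, f2
            x2 = None
        if b - a <= tol:
            break
        if x1 is None:
            x1 = a + (1.0 - _INVPHI) * (b - a)
            f1 = float(objective(x1))
            trace.log(x1, f1)
            if f1 < best_f:
                best_mu, best_f = x1, f1
        else:
            x2 = a + _INVPHI * (b - a)
            f2 = float(objective(x2))
            trace.log(x2, f2)
            if f2 < best_f:
                best_mu, best_f = x2, f2
    trace.final_mu, trace.final_objective = best_mu, best_f
    trace.final_interval = b - a
    return best_mu, trace


@dataclass
class InverseProblem:
    """Inverse problem definition.

    ``forward`` maps the axon shear modulus (kPa) to a simulated
    :class:`StressStretchCurve`; it must hold the RVE geometry, the coupling
    rule, and the load program fixed across evaluations.  If ``alpha``
    sensitivity scans are intended, ``forward_with_alpha(mu, alpha)`` must be
    provided as well.
    """

    target: StressStretchCurve
    forward: Callable[[float], StressStretchCurve]
    m: int = 20
    bracket: tuple[float, float] = (20.0, 50.0)
    tol: float = 1.0
    alpha_nominal: float = 8.22
    forward_with_alpha: Callable[[float, float], StressStretchCurve] | None = None

    def __post_init__(self):
        if self.bracket[0] > self.bracket[1]:
            raise ConfigurationError("bracket must satisfy mu_min <= mu_max")
        if self.tol <= 0 or self.m < 1:
            raise ConfigurationError("tol must be > 0 and m >= 1")

    def sample_points(self) -> np.ndarray:
        return sample_stretch_points(float(self.target.stretches[-1]), self.m)


def identify_shear_modulus(
    problem: InverseProblem,
    forward: Callable[[float], StressStretchCurve] | None = None,
) -> tuple[float, SearchTrace, StressStretchCurve]:
    """Golden-section minimization of the curve mismatch over the bracket.

    Returns ``(mu_star, trace, fitted_curve)`` where ``fitted_curve`` is the
    simulated curve at the optimum (served from the evaluation cache, so no
    extra forward solve is spent on it).
    """
    fwd = forward if forward is not None else problem.forward
    points = problem.sample_points()
    cache: dict[float, StressStretchCurve] = {}

    def run_forward(mu: float) -> StressStretchCurve:
        key = round(float(mu), 6)  # memoized at 1e-6 kPa granularity
        if key not in cache:
            cache[key] = fwd(mu)
        return cache[key]

    def objective(mu: float) -> float:
        return squared_error(problem.target, run_forward(mu), points)

    mu_star, trace = golden_section_search(objective, problem.bracket, problem.tol)
    return mu_star, trace, run_forward(mu_star)


def sensitivity_scan(problem: InverseProblem, alphas: Sequence[float]):
    """Repeat the identification for each Ogden exponent in ``alphas``.

    The target curve stays fixed; only the forward model's exponent changes.
    Returns a pandas DataFrame with columns ``alpha``, ``mu_star_kPa``,
    ``E_star_kPa2`` and ``rel_dev_pct`` (relative deviation of ``mu_star``
    from the nominal-alpha result, in percent).
    """
    import pandas as pd

    if problem.forward_with_alpha is None:
        raise ConfigurationError(
            "sensitivity_scan needs an InverseProblem with forward_with_alpha"
        )
    for alpha in alphas:
        if alpha <= 1.0:
            raise ConfigurationError(f"alpha must exceed 1, got {alpha}")

    rows = []
    results: dict[float, float] = {}
    scan = list(alphas)
    if problem.alpha_nominal not in scan:
        scan = [problem.alpha_nominal] + scan
    for alpha in scan:
        mu_star, trace, _ = identify_shear_modulus(
            problem, forward=lambda mu, a=alpha: problem.forward_with_alpha(mu, a)
        )
        results[alpha] = mu_star
        rows.append({"alpha": alpha, "mu_star_kPa": mu_star,
                     "E_star_kPa2": trace.final_objective})
    mu_nom = results[problem.alpha_nominal]
    df = pd.DataFrame(rows)
    df["rel_dev_pct"] = 100.0 * np.abs(df["mu_star_kPa"] - mu_nom) / mu_nom
    return df


def fit_parameters_simplex(objective, x0, bounds=None, tol: float = 1e-3):
    """Derivative-free multi-parameter fallback (Nelder-Mead).

    The single-variable identification uses golden-section search; this hook
    covers problems with several material parameters (e.g. fitting mu and
    alpha together) where a nonlinear least-squares/simplex method is the
    standard tool.  ``objective`` maps a parameter vector to a scalar
    mismatch; ``bounds`` (optional) is a list of (lo, hi) pairs enforced by
    clipping inside the wrapped objective.
    """
    from scipy.optimize import minimize

    x0 = np.asarray(x0, dtype=float)

    def wrapped(x):
        if bounds is not None:
            x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        return float(objective(x))

    res = minimize(wrapped, x0, method="Nelder-Mead",
                   options={"xatol": tol, "fatol": tol})
    x_best = res.x
    if bounds is not None:
        x_best = np.clip(x_best, [b[0] for b in bounds],
                         [b[1] for b in bounds])
    return x_best, float(res.fun)


def make_forward(
    rve: RVEGeometry,
    alpha: float = 8.22,
    mu_ratio_axon_to_ecm: float = 3.0,
    bulk_penalty_factor: float = 100.0,
    program: LoadProgram = LoadProgram(),
    rule: CouplingRule = CouplingRule(),
    element_size: float = 0.4,
    options: SolverOptions | None = None,
    selection_policy: str = "straightest",
    seed: int = 0,
) -> Callable[..., StressStretchCurve]:
    """Forward-model closure over a fixed RVE for the inverse loop.

    The returned callable maps ``mu_axon`` (optionally with an ``alpha``
    override as second argument) to the simulated homogenized curve; the RVE
    instance, mesh, coupling rule, and load program are frozen inside it.
    """

    def forward(mu_axon: float, alpha_override: float | None = None
                ) -> StressStretchCurve:
        mats = MaterialSet.from_axon_modulus(
            mu_axon,
            alpha if alpha_override is None else alpha_override,
            mu_ratio_axon_to_ecm=mu_ratio_axon_to_ecm,
            bulk_penalty_factor=bulk_penalty_factor,
        )
        result = staged_simulation(
            rve, mats, program=program, rule=rule, element_size=element_size,
            options=options, selection_policy=selection_policy, seed=seed,
        )
        return simulated_curve(result)

    return forward
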