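"""Transitional kinematic model (TKM) of axon-matrix coupling.

Experimentally, undulated axons in CNS white matter do not follow the bulk
tissue deformation (non-affine kinematics) until they have straightened
enough; coupling to the glial matrix then grows with applied stretch.  The
rule implemented here is a step table: an axon whose *current* undulation is
strictly below a threshold (default 1.08) has 8%, 20%, or 44% of its length
coupled to the matrix when the applied stretch is at most 1.06, 1.12, or
1.25 respectively; an axon above the threshold does not interact with the
matrix at all, except that its two end nodes are always tied to the matrix
at the RVE surfaces.  Coupling only ever grows: a sub-segment that has
coupled never releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .geometry import RVEGeometry, compute_tortuosity

__all__ = [
    "CouplingRule",
    "CouplingState",
    "coupling_fraction",
    "select_coupled_subsegments",
    "update_coupling_states",
]


@dataclass(frozen=True)
class CouplingRule:
    """Step table mapping (undulation, applied stretch) to coupled fraction."""

    threshold_undulation: float = 1.08
    stage_breaks: tuple[float, ...] = (1.06, 1.12, 1.25)
    stage_fractions: tuple[float, ...] = (0.08, 0.20, 0.44)

    def __post_init__(self):
        if len(self.stage_breaks) != len(self.stage_fractions):
            raise ConfigurationError("stage_breaks and stage_fractions lengths differ")
        if np.any(np.diff(self.stage_breaks) <= 0):
            raise ConfigurationError("stage_breaks must be strictly increasing")
        fr = np.asarray(self.stage_fractions)
        if np.any(fr < 0) or np.any(fr > 1) or np.any(np.diff(fr) < 0):
            raise ConfigurationError(
                "stage_fractions must be in [0, 1] and non-decreasing"
            )


def coupling_fraction(undulation: float, applied_stretch: float,
                      rule: CouplingRule = CouplingRule()) -> float:
    """Coupled length fraction for an axon at the given state.

    Zero for undulation at or above the threshold (the inequality in the
    rule is strict).  Otherwise the fraction of the smallest stage break
    that is >= the applied stretch; stretches beyond the last break use the
    last fraction.
    """
    if applied_stretch < 1.0:
        raise ValueError(f"applied stretch must be >= 1, got {applied_stretch}")
    if undulation < 1.0 - 1e-9:
        raise ValueError(f"undulation must be >= 1, got {undulation}")
    if not undulation < rule.threshold_undulation:
        return 0.0
    for brk, frac in zip(rule.stage_breaks, rule.stage_fractions):
        if applied_stretch <= brk:
            return frac
    return rule.stage_fractions[-1]


def _target_count(fraction: float, n: int) -> int:
    return int(np.floor(fraction * n + 0.5))


def select_coupled_subsegments(
    path,
    fraction: float,
    seed: int = 0,
    policy: str = "straightest",
    previous: frozenset[int] | None = None,
) -> frozenset[int]:
    """Pick which sub-segments carry the coupled fraction.

    ``round(fraction * n)`` segments are selected.  Policies:

    - ``"straightest"`` (default): lowest local (reference) sub-segment
      tortuosity first, ties broken by index -- straight portions reach
      affine kinematics first.
    - ``"random"``: uniformly at random, reproducible for a fixed seed.
    - ``"from-ends"``: alternately from the two fiber ends inward.

    If ``previous`` is given the returned set is a superset of it: segments
    already coupled stay coupled and only the shortfall is newly selected.
    """
    n = path.n_subsegments
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in [0, 1], got {fraction}")
    prev = frozenset() if previous is None else frozenset(previous)
    k = _target_count(fraction, n)
    if k <= len(prev):
        return prev

    if policy == "straightest":
        local = path.subsegment_tortuosities()
        order = np.lexsort((np.arange(n), local))
    elif policy == "random":
        order = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(0x5E1EC7,))
        ).permutation(n)
    elif policy == "from-ends":
        half = (n + 1) // 2
        order = np.empty(n, dtype=int)
        order[0::2] = np.arange(half)
        order[1::2] = n - 1 - np.arange(n - half)
    else:
        raise ConfigurationError(f"unknown segment-selection policy {policy!r}")

    chosen = set(prev)
    for idx in order:
        if len(chosen) >= k:
            break
        chosen.add(int(idx))
    return frozenset(chosen)


@dataclass(frozen=True)
class CouplingState:
    """Coupling snapshot of the whole axon population at one applied stretch."""

    applied_stretch: float
    tortuosities: np.ndarray                  # current per-axon undulation
    fractions: np.ndarray                     # rule output per axon
    coupled_sets: tuple[frozenset[int], ...]  # coupled sub-segment ids per axon
    records: tuple[dict, ...] = field(default=())

    def coupled_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.coupled_sets])


def update_coupling_states(
    rve: RVEGeometry,
    deformed_nodes,
    applied_stretch: float,
    rule: CouplingRule = CouplingRule(),
    previous: CouplingState | None = None,
    policy: str = "straightest",
    seed: int = 0,
) -> CouplingState:
    """Re-evaluate the TKM for every axon from its current deformed shape.

    ``deformed_nodes`` is a sequence of (n_subsegments + 1, 3) arrays holding
    the current positions of each axon's sub-segment boundary nodes; the
    per-axon undulation is recomputed from that polyline.  Coupled sets grow
    monotonically relative to ``previous``.  One log record per axon is
    appended to the returned state's ``records``.
    """
    torts, fracs, sets, records = [], [], [], []
    for i, (path, nodes) in enumerate(zip(rve.axons, deformed_nodes)):
        und = compute_tortuosity(nodes)
        frac = coupling_fraction(und, applied_stretch, rule)
        prev = previous.coupled_sets[i] if previous is not None else None
        coupled = select_coupled_subsegments(
            path, frac, seed=seed + i, policy=policy, previous=prev
        )
        torts.append(und)
        fracs.append(frac)
        sets.append(coupled)
        records.append(
            {
                "axon": i,
                "applied_stretch": applied_stretch,
                "undulation": und,
                "fraction": frac,
                "coupled_count": len(coupled),
            }
        )
    return CouplingState(
        applied_stretch=applied_stretch,
        tortuosities=np.array(torts),
        fractions=np.array(fracs),
        coupled_sets=tuple(sets),
        records=tuple(records),
    )
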