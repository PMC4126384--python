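"""Randomized pseudo-3D RVE geometry of undulated axons in a cuboid matrix.

The representative volume element is a thin cuboid (default
0.4 x 10 x 5.68 um) spanned by axon fibers that run from the z = 0 face to
the z = size_z face.  Each axon is built from a small number of randomly
perturbed waypoints, smoothed by a cubic spline, and characterized by its
tortuosity (arc length over end-to-end chord length, >= 1).  Axons are added
one at a time, with target tortuosities drawn from a configurable truncated
normal distribution, until the swept-circle volume of the population reaches
the requested volume fraction (default 53%).  Fiber overlap is ignored in
the volume accounting because the downstream embedded-element solver does not
remove matrix material where fibers reside.

Because a single fixed-diameter axon changes the volume fraction by several
percentage points, the last axon's radius is reduced so the achieved fraction
matches the target exactly; all earlier axons keep the nominal diameter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import truncnorm

from .errors import CalibrationError, ConfigurationError, InvalidGeometryError

__all__ = [
    "BoxDomain",
    "AxonPath",
    "RVEGeometry",
    "compute_tortuosity",
    "generate_axon_path",
    "clip_to_domain",
    "axon_volume",
    "partition_subsegments",
    "build_rve",
]

#: default number of dense centerline samples; chosen so that snapping the 50
#: equal-arc sub-segment boundaries to sample indices perturbs piece lengths
#: by well under 1%.
N_CENTERLINE_SAMPLES = 4001


@dataclass(frozen=True)
class BoxDomain:
    """Cuboid matrix domain with edge lengths in micrometres."""

    size_x: float = 0.4
    size_y: float = 10.0
    size_z: float = 5.68

    def __post_init__(self):
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ConfigurationError("all box dimensions must be positive")

    @property
    def volume(self) -> float:
        return self.size_x * self.size_y * self.size_z

    @property
    def sizes(self) -> np.ndarray:
        return np.array([self.size_x, self.size_y, self.size_z])


@dataclass(frozen=True)
class AxonPath:
    """One undulated axon fiber.

    ``centerline`` holds dense ordered samples of the cubic-spline backbone;
    ``subsegment_bounds`` are centerline indices delimiting the equal-arc
    sub-segments used by the coupling model (length ``n_subsegments + 1``).
    """

    waypoints: np.ndarray
    centerline: np.ndarray
    radius: float = 0.2
    tortuosity: float = 1.0
    subsegment_bounds: np.ndarray | None = None

    @property
    def n_subsegments(self) -> int:
        return 0 if self.subsegment_bounds is None else len(self.subsegment_bounds) - 1

    @property
    def subsegment_nodes(self) -> np.ndarray:
        """Centerline points at the sub-segment boundaries, shape (n+1, 3)."""
        if self.subsegment_bounds is None:
            raise InvalidGeometryError("axon has no sub-segment partition")
        return self.centerline[self.subsegment_bounds]

    def subsegment_tortuosities(self) -> np.ndarray:
        """Local arc/chord ratio of each sub-segment (reference geometry)."""
        bounds = self.subsegment_bounds
        if bounds is None:
            raise InvalidGeometryError("axon has no sub-segment partition")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arc = np.diff(cum[bounds])
        chord = np.linalg.norm(
            self.centerline[bounds[1:]] - self.centerline[bounds[:-1]], axis=1
        )
        return arc / np.maximum(chord, 1e-300)


def compute_tortuosity(points) -> float:
    """Arc length of an ordered point sequence over its end-to-end distance.

    Raises :class:`InvalidGeometryError` for fewer than two points or
    coincident endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidGeometryError("tortuosity needs at least two ordered points")
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord <= 0.0:
        raise InvalidGeometryError("coincident endpoints: end-to-end distance is zero")
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    return arc / chord


def axon_volume(path: AxonPath) -> float:
    """Swept-circle volume pi r^2 L (um^3), ignoring curvature and overlap."""
    if path.radius < 0:
        raise InvalidGeometryError("negative radius")
    if path.radius == 0.0:
        return 0.0
    arc = float(np.linalg.norm(np.diff(path.centerline, axis=0), axis=1).sum())
    return np.pi * path.radius**2 * arc


def _clip_points(points: np.ndarray, domain: BoxDomain) -> np.ndarray:
    return np.clip(points, 0.0, domain.sizes)


def clip_to_domain(path: AxonPath, domain: BoxDomain) -> AxonPath:
    """Project out-of-bounds centerline coordinates onto the box faces.

    Clipping acts on the fiber axis (not a swept solid) and can only shorten
    transverse excursions, so the clipped tortuosity never meaningfully
    exceeds the unclipped one.  Tortuosity is recomputed on the clipped
    centerline.
    """
    clipped = _clip_points(np.asarray(path.centerline, dtype=float), domain)
    if clipped.shape[0] < 2:
        raise InvalidGeometryError("path is empty after clipping")
    return replace(
        path,
        centerline=clipped,
        waypoints=_clip_points(np.asarray(path.waypoints, dtype=float), domain),
        tortuosity=compute_tortuosity(clipped),
    )


def partition_subsegments(path: AxonPath, n: int = 50) -> AxonPath:
    """Split the centerline into ``n`` contiguous pieces of equal arc length.

    Boundaries are snapped to centerline sample indices; the last piece
    absorbs the rounding remainder.
    """
    if n < 1:
        raise ConfigurationError(f"number of sub-segments must be >= 1, got {n}")
    seg = np.linalg.norm(np.diff(path.centerline, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise InvalidGeometryError("centerline arc length is zero")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n + 1)
    bounds = np.searchsorted(cum, targets, side="left")
    # snap to the nearer neighbour and enforce strict monotonicity
    for k in range(1, n):
        i = bounds[k]
        if i > 0 and abs(cum[i - 1] - targets[k]) < abs(cum[i] - targets[k]):
            bounds[k] = i - 1
    bounds[0], bounds[-1] = 0, len(cum) - 1
    bounds = np.maximum.accumulate(bounds)
    if np.any(np.diff(bounds) < 1):
        raise InvalidGeometryError(
            "centerline too coarsely sampled for the requested sub-segment count"
        )
    return replace(path, subsegment_bounds=bounds.astype(int))


def _spline_centerline(waypoints: np.ndarray, n_samples: int) -> np.ndarray:
    """Cubic-spline smoothing of waypoints, parameterized by the z coordinate.

    The dense samples are re-parameterized to uniform arc length so that
    snapping sub-segment boundaries to sample indices keeps the pieces equal
    to high accuracy.
    """
    z = waypoints[:, 2]
    cs_x = CubicSpline(z, waypoints[:, 0])
    cs_y = CubicSpline(z, waypoints[:, 1])
    zs = np.linspace(z[0], z[-1], 4 * n_samples)
    dense = np.column_stack([cs_x(zs), cs_y(zs), zs])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s_eq = np.linspace(0.0, cum[-1], n_samples)
    return np.column_stack([np.interp(s_eq, cum, dense[:, d]) for d in range(3)])


def generate_axon_path(
    seed: int | np.random.SeedSequence,
    target_tortuosity: float,
    domain: BoxDomain = BoxDomain(),
    n_waypoints: int = 8,
    radius: float = 0.2,
    n_subsegments: int = 50,
    tol: float = 2e-3,
    n_samples: int = N_CENTERLINE_SAMPLES,
) -> AxonPath:
    """Generate one undulated axon spanning the z faces of the domain.

    The fiber starts at a random point on the z = 0 face and ends directly
    opposite on the z = size_z face; ``n_waypoints`` interior waypoints at
    uniform z spacing receive random transverse offsets whose common
    amplitude is scaled by bisection until the splined-and-clipped centerline
    realizes ``target_tortuosity`` within ``tol``.  Offsets in x are shrunk
    by the box aspect ratio so the fiber stays within the thin dimension.

    Raises :class:`CalibrationError` (carrying the maximum attainable value)
    if the target cannot be reached.
    """
    if target_tortuosity < 1.0:
        raise ConfigurationError("target tortuosity must be >= 1")
    if n_waypoints < 1:
        raise ConfigurationError("need at least one interior waypoint")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, domain.size_x)
    y0 = rng.uniform(0.0, domain.size_y)
    z = np.linspace(0.0, domain.size_z, n_waypoints + 2)
    # unscaled transverse offsets; endpoints stay at (x0, y0)
    dy = np.zeros(n_waypoints + 2)
    dx = np.zeros(n_waypoints + 2)
    dy[1:-1] = rng.standard_normal(n_waypoints)
    dx[1:-1] = rng.standard_normal(n_waypoints) * (domain.size_x / domain.size_y)

    def realized(s: float) -> tuple[float, np.ndarray, np.ndarray]:
        wp = np.column_stack([x0 + s * dx, y0 + s * dy, z])
        cl = _clip_points(_spline_centerline(wp, n_samples), domain)
        return compute_tortuosity(cl), wp, cl

    if target_tortuosity == 1.0:
        s_star = 0.0
    else:
        s_lo, s_hi = 0.0, 0.05 * domain.size_y
        t_hi = realized(s_hi)[0]
        while t_hi < target_tortuosity and s_hi < 4.0 * domain.size_y:
            s_hi *= 2.0
            t_hi = realized(s_hi)[0]
        if t_hi < target_tortuosity:
            raise CalibrationError(
                f"target tortuosity {target_tortuosity} unreachable; "
                f"maximum attainable is {t_hi:.4f}",
                max_attainable=t_hi,
            )
        for _ in range(80):
            s_mid = 0.5 * (s_lo + s_hi)
            if realized(s_mid)[0] < target_tortuosity:
                s_lo = s_mid
            else:
                s_hi = s_mid
        s_star = 0.5 * (s_lo + s_hi)

    t_star, wp, cl = realized(s_star)
    if abs(t_star - target_tortuosity) > tol:
        raise CalibrationError(
            f"undulation calibration stalled at {t_star:.4f} "
            f"(target {target_tortuosity}); clipping may be flattening the path",
            max_attainable=t_star,
        )
    path = AxonPath(
        waypoints=_clip_points(wp, domain),
        centerline=cl,
        radius=radius,
        tortuosity=t_star,
    )
    return partition_subsegments(path, n_subsegments)


@dataclass(frozen=True)
class RVEGeometry:
    """Cuboid domain plus axon population and the generation bookkeeping."""

    domain: BoxDomain
    axons: tuple[AxonPath, ...]
    target_volume_fraction: float
    achieved_volume_fraction: float
    seed: int

    @property
    def n_axons(self) -> int:
        return len(self.axons)

    def tortuosities(self) -> np.ndarray:
        return np.array([a.tortuosity for a in self.axons])

    def to_dict(self) -> dict:
        return {
            "domain": [self.domain.size_x, self.domain.size_y, self.domain.size_z],
            "target_volume_fraction": self.target_volume_fraction,
            "achieved_volume_fraction": self.achieved_volume_fraction,
            "seed": self.seed,
            "axons": [
                {
                    "waypoints": a.waypoints.tolist(),
                    "centerline": a.centerline.tolist(),
                    "radius": a.radius,
                    "tortuosity": a.tortuosity,
                    "subsegment_bounds": (
                        None if a.subsegment_bounds is None
                        else a.subsegment_bounds.tolist()
                    ),
                }
                for a in self.axons
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RVEGeometry":
        domain = BoxDomain(*d["domain"])
        axons = tuple(
            AxonPath(
                waypoints=np.asarray(a["waypoints"], dtype=float),
                centerline=np.asarray(a["centerline"], dtype=float),
                radius=a["radius"],
                tortuosity=a["tortuosity"],
                subsegment_bounds=(
                    None if a["subsegment_bounds"] is None
                    else np.asarray(a["subsegment_bounds"], dtype=int)
                ),
            )
            for a in d["axons"]
        )
        return cls(
            domain=domain,
            axons=axons,
            target_volume_fraction=d["target_volume_fraction"],
            achieved_volume_fraction=d["achieved_volume_fraction"],
            seed=d["seed"],
        )

    @classmethod
    def from_json(cls, text_or_path) -> "RVEGeometry":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


def build_rve(config, seed: int) -> RVEGeometry:
    """Generate a randomized RVE from a geometry configuration.

    ``config`` is any object exposing the geometry-block attributes of
    :class:`axonrve.config.GeometryConfig`: ``domain`` sizes, ``radius``,
    ``target_volume_fraction``, ``packing_bound``, the truncated-normal
    undulation distribution (``undulation_mean``, ``undulation_sd``,
    ``undulation_low``, ``undulation_high``), ``n_waypoints`` and
    ``n_subsegments``.

    Axons are appended until the summed swept-circle volume first reaches the
    target fraction; the final axon's radius is then reduced so the achieved
    fraction equals the target exactly.  Per-axon random streams are derived
    from ``seed`` by a counter scheme (``SeedSequence(seed, spawn_key=(i,))``),
    so axon ``i`` is independent of how many axons follow it.
    """
    domain = BoxDomain(*config.domain) if not isinstance(getattr(config, "domain"), BoxDomain) else config.domain
    vf = config.target_volume_fraction
    if vf < 0:
        raise ConfigurationError("target volume fraction must be non-negative")
    if vf > config.packing_bound:
        raise ConfigurationError(
            f"target volume fraction {vf} exceeds the configured packing bound "
            f"{config.packing_bound}"
        )
    if config.undulation_low < 1.0:
        raise ConfigurationError("undulation distribution support must start at >= 1.0")

    v_box = domain.volume
    v_target = vf * v_box
    axons: list[AxonPath] = []
    v_sum = 0.0
    i = 0
    while v_sum < v_target and vf > 0:
        ss = np.random.SeedSequence(seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        a = (config.undulation_low - config.undulation_mean) / config.undulation_sd
        b = (config.undulation_high - config.undulation_mean) / config.undulation_sd
        target_t = float(
            truncnorm.rvs(
                a, b, loc=config.undulation_mean, scale=config.undulation_sd,
                random_state=rng,
            )
        )
        path = generate_axon_path(
            ss.spawn(1)[0],
            target_t,
            domain=domain,
            n_waypoints=config.n_waypoints,
            radius=config.radius,
            n_subsegments=config.n_subsegments,
        )
        v = axon_volume(path)
        if v_sum + v >= v_target:
            # shrink the closing axon's radius so the fraction lands exactly
            arc = v / (np.pi * path.radius**2)
            r_close = float(np.sqrt((v_target - v_sum) / (np.pi * arc)))
            path = replace(path, radius=r_close)
            v = axon_volume(path)
        axons.append(path)
        v_sum += v
        i += 1

    return RVEGeometry(
        domain=domain,
        axons=tuple(axons),
        target_volume_fraction=vf,
        achieved_volume_fraction=v_sum / v_box,
        seed=int(seed),
    )
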