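"""Feedforward-related synergies: dimensionality of feasible activation sets.

Even with no perturbations and no reflexes, an isometric force task
constrains which activation patterns are *possible*.  For force targets of a
fixed magnitude in many planar directions (torque and out-of-plane
components pinned to zero), each target's solution set is a polytope in
[0,1]^n; pooling the vertices of those polytopes across all directions and
running PCA shows that the complete space of motor options is itself
low-dimensional.  An experimenter sampling forces omnidirectionally at set
magnitudes therefore observes low-dimensional muscle activity regardless of
how the nervous system picks within the solution sets.

The scan mirrors the experimental procedure: force magnitude is increased
in fixed increments (1 N for a finger, 50 N for a leg) until some direction
admits no solution, i.e. the levels are the concentric circles that fit
inside the feasible force set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DimensionError
from .limb import ActionMatrix, LimbModel, action_matrix
from .pca import PcaBasis, pca_fit
from .polytope import (
    VERTEX_ENUMERATION_MUSCLE_CAP,
    VertexSet,
    build_activation_polytope,
    enumerate_vertices,
    max_feasible_magnitude,
)

__all__ = [
    "ForceScan",
    "SolutionPca",
    "planar_directions",
    "scan_force_levels",
    "combined_solution_pca",
    "bootstrap_ci",
    "FeedforwardSynergy",
    "FeedforwardSynergyResults",
]


def planar_directions(k: int) -> np.ndarray:
    """k unit vectors at equally spaced planar angles starting at angle 0."""
    if k < 2:
        raise ConfigError("need at least 2 force directions")
    ang = 2.0 * np.pi * np.arange(k) / k
    return np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass
class ForceScan:
    """Feasible force levels common to all scanned directions.

    ``levels`` are the positive multiples of ``increment`` that fit within
    the feasible force set in *every* direction (concentric circles inside
    the feasible force polygon); ``max_feasible_per_direction`` holds the LP
    boundary distance along each direction.
    """

    directions: np.ndarray
    increment: float
    levels: np.ndarray
    max_feasible_per_direction: np.ndarray
    zero_components: tuple[str, ...] = ("tz",)

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.levels = np.atleast_1d(np.asarray(self.levels, dtype=float))
        self.max_feasible_per_direction = np.atleast_1d(
            np.asarray(self.max_feasible_per_direction, dtype=float)
        )

    @property
    def k_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.levels.size == 0


def scan_force_levels(
    action: ActionMatrix,
    k_directions: int = 16,
    increment: float = 1.0,
    zero_components: tuple[str, ...] = ("tz",),
) -> ForceScan:
    """Scan force magnitudes in fixed increments over equally spaced
    directions, keeping every level feasible in all directions."""
    if increment <= 0:
        raise ConfigError("increment must be positive")
    dirs = planar_directions(k_directions)
    max_mag = np.array(
        [max_feasible_magnitude(action, u, zero_components) for u in dirs]
    )
    limit = float(np.min(max_mag))
    n_levels = int(np.floor(limit / increment + 1e-12))
    if n_levels < 1:
        warnings.warn(
            f"no feasible force level: min feasible magnitude {limit:.3g} N is below "
            f"the increment {increment:.3g} N",
            stacklevel=2,
        )
        levels = np.empty(0)
    else:
        levels = increment * np.arange(1, n_levels + 1)
    return ForceScan(dirs, increment, levels, max_mag, tuple(zero_components))


@dataclass
class SolutionPca:
    """Dimensionality of pooled activation solution sets, per force level."""

    levels: np.ndarray
    n_vertices: list[int]
    cumulative_vaf: list[np.ndarray]
    n_components: list[int]
    threshold: float
    bases: list[PcaBasis] = field(default_factory=list)
    excluded_levels: list[float] = field(default_factory=list)
    pooled_cumulative_vaf: np.ndarray | None = None
    pooled_n_components: int | None = None


def _pooled_pca(cloud: np.ndarray, threshold: float, centered: bool):
    """PCA of a vertices x muscles cloud; returns (basis, cum curve, n_comp)."""
    basis = pca_fit(cloud.T, centered=centered)
    cum = basis.cumulative_variance()
    above = np.nonzero(cum > threshold)[0]
    n_comp = int(above[0]) + 1 if len(above) else basis.n_components
    return basis, cum, n_comp


def combined_solution_pca(
    action: ActionMatrix,
    scan: ForceScan,
    threshold: float = 0.8,
    per_level: bool = True,
    centered: bool = True,
    cap: int = VERTEX_ENUMERATION_MUSCLE_CAP,
) -> SolutionPca:
    """PCA of solution-set vertices pooled across all force directions.

    For each level of the scan, the vertex sets of the activation polytopes
    for all directions are pooled (with their natural multiplicity, no
    reweighting) and PCA is run on the pooled cloud in muscle space.  When
    ``per_level`` is False the clouds are additionally pooled across levels.
    Levels contributing fewer than 2 vertices in total are excluded with a
    warning.
    """
    if scan.is_empty:
        raise ConfigError("the force scan has no feasible levels")
    levels, counts, curves, comps, bases = [], [], [], [], []
    all_clouds = []
    for level in scan.levels:
        cloud_rows = []
        for u in scan.directions:
            poly = build_activation_polytope(action, u, float(level), scan.zero_components)
            vs = enumerate_vertices(poly, cap=cap)
            if vs.is_feasible:
                cloud_rows.append(vs.vertices)
        cloud = np.vstack(cloud_rows) if cloud_rows else np.empty((0, action.n_muscles))
        if cloud.shape[0] < 2:
            warnings.warn(
                f"level {level:g} N excluded: fewer than 2 solution vertices",
                stacklevel=2,
            )
            continue
        all_clouds.append(cloud)
        basis, cum, n_comp = _pooled_pca(cloud, threshold, centered)
        levels.append(float(level))
        counts.append(cloud.shape[0])
        curves.append(cum)
        comps.append(n_comp)
        bases.append(basis)
    result = SolutionPca(
        levels=np.array(levels),
        n_vertices=counts,
        cumulative_vaf=curves,
        n_components=comps,
        threshold=threshold,
        bases=bases,
        excluded_levels=[float(l) for l in scan.levels if float(l) not in levels],
    )
    if not per_level and all_clouds:
        _, cum, n_comp = _pooled_pca(np.vstack(all_clouds), threshold, centered)
        result.pooled_cumulative_vaf = cum
        result.pooled_n_components = n_comp
    return result


def bootstrap_ci(
    samples: np.ndarray,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    statistic=np.mean,
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap confidence interval.

    Resamples the provided per-unit statistics (e.g. per-specimen or
    per-posture component counts) with replacement and returns the
    ``(1 - level)/2`` and ``(1 + level)/2`` quantiles of the bootstrap
    distribution of ``statistic``.
    """
    x = np.atleast_1d(np.asarray(samples, dtype=float))
    if x.size < 2:
        raise ConfigError("bootstrap needs at least 2 samples")
    if not 0.0 < level < 1.0:
        raise ConfigError("confidence level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    stats = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.quantile(stats, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class FeedforwardSynergy:
    """Feedforward-related synergy analysis of one limb (or action matrix).

    Parameters
    ----------
    model : LimbModel or ActionMatrix
        The limb at a posture (its action matrix is derived), or an action
        matrix estimated directly, e.g. from a tension protocol.
    k_directions : int
        Number of equally spaced planar force directions (default 16).
    increment : float
        Force-magnitude step in newtons (1 N finger-scale, 50 N leg-scale).
    zero_components : tuple of wrench labels pinned to zero (torques and any
        out-of-plane forces).
    """

    def __init__(
        self,
        model: LimbModel | ActionMatrix,
        k_directions: int = 16,
        increment: float = 1.0,
        zero_components: tuple[str, ...] = ("tz",),
        centered: bool = True,
        cap: int = VERTEX_ENUMERATION_MUSCLE_CAP,
    ):
        self.action = model if isinstance(model, ActionMatrix) else action_matrix(model)
        if self.action.n_muscles > cap:
            raise DimensionError(
                f"{self.action.n_muscles} muscles exceed the enumeration cap ({cap}); "
                "group muscles before the feedforward analysis"
            )
        self.k_directions = k_directions
        self.increment = increment
        self.zero_components = tuple(zero_components)
        self.centered = centered
        self.cap = cap

    def fit(self, threshold: float = 0.8, per_level: bool = True) -> "FeedforwardSynergyResults":
        scan = scan_force_levels(
            self.action, self.k_directions, self.increment, self.zero_components
        )
        if scan.is_empty:
            return FeedforwardSynergyResults(self, scan, None, threshold)
        sol = combined_solution_pca(
            self.action, scan, threshold=threshold, per_level=per_level,
            centered=self.centered, cap=self.cap,
        )
        return FeedforwardSynergyResults(self, scan, sol, threshold)


@dataclass
class FeedforwardSynergyResults:
    """Force scan plus per-level dimensionality of the pooled solution sets."""

    model: FeedforwardSynergy
    scan: ForceScan
    solution_pca: SolutionPca | None
    threshold: float

    @property
    def n_components_per_level(self) -> np.ndarray:
        if self.solution_pca is None:
            return np.empty(0, dtype=int)
        return np.asarray(self.solution_pca.n_components, dtype=int)

    def n_components_ci(self, level: float = 0.95, n_boot: int = 2000, seed: int = 0):
        """Percentile bootstrap CI of the mean component count across levels."""
        return bootstrap_ci(self.n_components_per_level, level, n_boot, seed)

    def summary(self) -> str:
        act = self.model.action
        lines = [
            "Feedforward-related synergy analysis",
            "=" * 52,
            f"muscles:            {act.n_muscles}",
            f"force directions:   {self.scan.k_directions}",
            f"increment:          {self.scan.increment:g} N",
            f"zeroed components:  {', '.join(self.model.zero_components) or 'none'}",
            f"min feasible bound: {np.min(self.scan.max_feasible_per_direction):.3f} N",
        ]
        if self.solution_pca is None or len(self.solution_pca.levels) == 0:
            lines.append("no feasible force level — empty scan")
            return "\n".join(lines)
        lines += [
            f"feasible levels:    {len(self.solution_pca.levels)}",
            "",
            f"  level(N)   vertices   components for >{self.threshold:.0%}",
        ]
        for lev, nv, nc in zip(
            self.solution_pca.levels,
            self.solution_pca.n_vertices,
            self.solution_pca.n_components,
        ):
            lines.append(f"  {lev:8.2f}   {nv:8d}   {nc:5d}")
        if self.solution_pca.pooled_n_components is not None:
            lines.append(
                f"pooled across levels: {self.solution_pca.pooled_n_components} components"
            )
        return "\n".join(lines)
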