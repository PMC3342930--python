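"""Feasible-activation polytopes and exact vertex enumeration.

For an action matrix ``A`` (wrench per unit activation) and a target wrench
``w``, the set of activation patterns producing ``w`` is the polytope

    P = { a in [0,1]^n : A_eq a = b_eq }

where ``A_eq``/``b_eq`` pin the in-plane force to ``magnitude * direction``
and the remaining listed wrench components (out-of-plane forces, torques)
to zero.  ``P`` is the complete, redundant set of motor options for one
task; its vertices are its canonical finite description (they span its
affine hull), and PCA over vertices pooled across many force directions is
what reveals the feedforward dimensionality constraint.

Vertex enumeration here is exact: inputs are converted to rationals
(binary floats convert exactly), the equalities are eliminated by Gaussian
reduction, and the remaining box of free coordinates is cut one inequality
at a time.  After each cut, candidate points are kept only if the gradients
of their tight constraints span the reduced space — the basic-feasible-
solution characterization of a vertex — so degenerate polytopes (many tight
bounds at once, the norm for activation problems) are handled without
tolerance juggling.  Complexity is exponential in ``n - rank(A_eq)``; the
muscle count is capped (default 16) with an explicit refusal, the same
compromise that forces many-muscle models down to grouped versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import numpy as np
from scipy.optimize import linprog

from .errors import ConfigError, DimensionError, MechSynergyError, SizeCapError
from .limb import ActionMatrix

__all__ = [
    "ActivationPolytope",
    "VertexSet",
    "build_activation_polytope",
    "enumerate_vertices",
    "max_feasible_magnitude",
]

#: Default refusal threshold for exact enumeration (exponential cost).
VERTEX_ENUMERATION_MUSCLE_CAP = 16

#: Vertices closer than this (in activation units, max-norm) are merged.
VERTEX_DEDUP_TOL = 1e-8


@dataclass
class ActivationPolytope:
    """H-representation of {a in [0,1]^n : A_eq a = b_eq}."""

    a_eq: np.ndarray
    b_eq: np.ndarray
    target_label: tuple | None = None

    def __post_init__(self) -> None:
        self.a_eq = np.atleast_2d(np.asarray(self.a_eq, dtype=float))
        self.b_eq = np.atleast_1d(np.asarray(self.b_eq, dtype=float))
        if self.a_eq.shape[0] != self.b_eq.shape[0]:
            raise DimensionError("a_eq and b_eq disagree on the number of equalities")
        if not (np.all(np.isfinite(self.a_eq)) and np.all(np.isfinite(self.b_eq))):
            raise DimensionError("polytope coefficients must be finite")

    @property
    def n_muscles(self) -> int:
        return self.a_eq.shape[1]

    @property
    def n_equalities(self) -> int:
        return self.a_eq.shape[0]


@dataclass
class VertexSet:
    """All vertices of an activation polytope, lexicographically sorted.

    An empty set signals infeasibility; a single row is the degenerate
    point-polytope case.
    """

    vertices: np.ndarray
    target_label: tuple | None = None
    n_muscles: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.size == 0:
            self.vertices = self.vertices.reshape(0, self.n_muscles)
        else:
            self.vertices = np.atleast_2d(self.vertices)
            self.n_muscles = self.vertices.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def is_feasible(self) -> bool:
        return self.n_vertices > 0


def build_activation_polytope(
    action: ActionMatrix,
    direction: np.ndarray,
    magnitude: float,
    zero_components: tuple[str, ...] = ("tz",),
) -> ActivationPolytope:
    """Equality constraints for a planar force task.

    The wrench rows *not* listed in ``zero_components`` form the force plane
    and are pinned to ``magnitude * direction`` (``direction`` unit norm in
    that plane); every listed component is pinned to exactly 0 (out-of-plane
    forces to keep the task planar, torques so the force could be applied
    statically to an unattached object).
    """
    labels = list(action.wrench_labels)
    for z in zero_components:
        if z not in labels:
            raise ConfigError(f"unknown wrench component {z!r}; model has {labels}")
    plane = [i for i, lab in enumerate(labels) if lab not in zero_components]
    zero = [i for i, lab in enumerate(labels) if lab in zero_components]
    u = np.atleast_1d(np.asarray(direction, dtype=float))
    if u.shape != (len(plane),):
        raise DimensionError(
            f"direction has {u.shape[0]} components for a {len(plane)}-dimensional force plane"
        )
    if magnitude > 0 and not np.isclose(np.linalg.norm(u), 1.0, atol=1e-9):
        raise ConfigError("direction must be a unit vector in the force plane")
    A = action.matrix
    a_eq = np.vstack([A[plane, :], A[zero, :]])
    b_eq = np.concatenate([magnitude * u, np.zeros(len(zero))])
    return ActivationPolytope(a_eq, b_eq, target_label=(tuple(np.round(u, 12)), float(magnitude)))


# ---------------------------------------------------------------------------
# exact rational linear algebra helpers
# ---------------------------------------------------------------------------

def _rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form over the rationals; returns (rows, pivot columns)."""
    rows = [list(r) for r in rows]
    n_rows = len(rows)
    n_cols = len(rows[0]) if n_rows else 0
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pr = next((i for i in range(r, n_rows) if rows[i][c] != 0), None)
        if pr is None:
            continue
        rows[r], rows[pr] = rows[pr], rows[r]
        pv = rows[r][c]
        rows[r] = [x / pv for x in rows[r]]
        for i in range(n_rows):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [x - f * y for x, y in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    return rows, pivots


def _rank(rows: list[tuple[Fraction, ...]]) -> int:
    if not rows:
        return 0
    _, piv = _rref([list(r) for r in rows])
    return len(piv)


def enumerate_vertices(
    polytope: ActivationPolytope,
    cap: int = VERTEX_ENUMERATION_MUSCLE_CAP,
    dedup_tol: float = VERTEX_DEDUP_TOL,
) -> VertexSet:
    """Exact vertex set of {a in [0,1]^n : A_eq a = b_eq}.

    Returns vertices in lexicographic order.  An empty result means the
    polytope is infeasible (distinct from a feasible single-point polytope,
    which returns exactly one vertex).
    """
    n = polytope.n_muscles
    if n > cap:
        raise SizeCapError(
            f"refusing exact vertex enumeration for {n} muscles (cap {cap}); "
            "complexity grows exponentially — group muscles first"
        )
    A = [[Fraction(float(x)) for x in row] for row in polytope.a_eq]
    b = [Fraction(float(x)) for x in polytope.b_eq]

    # eliminate equalities: rref of [A | b]
    aug, pivots = _rref([row + [bi] for row, bi in zip(A, b)]) if A else ([], [])
    if n in pivots:  # pivot in the rhs column: inconsistent system
        return VertexSet(np.empty((0, n)), polytope.target_label, n_muscles=n)
    pivots = [p for p in pivots if p < n]
    free = [j for j in range(n) if j not in pivots]
    d = len(free)

    # coordinate j as an affine function of the free coordinates t:
    # a_j = coef[j] . t + const[j]
    coef = [[Fraction(0)] * d for _ in range(n)]
    const = [Fraction(0)] * n
    for k, j in enumerate(free):
        coef[j][k] = Fraction(1)
    for row, p in zip(aug, pivots):
        const[p] = row[n]
        for k, j in enumerate(free):
            coef[p][k] = -row[j]

    if d == 0:
        a = const
        if all(0 <= x <= 1 for x in a):
            return VertexSet(
                np.array([[float(x) for x in a]]), polytope.target_label, n_muscles=n
            )
        return VertexSet(np.empty((0, n)), polytope.target_label, n_muscles=n)

    # inequalities g.t <= h for 0 <= a_j <= 1
    ineqs: list[tuple[tuple[Fraction, ...], Fraction]] = []
    for j in range(n):
        g = tuple(-c for c in coef[j])
        ineqs.append((g, const[j]))  # a_j >= 0  <=>  -coef.t <= const
        g = tuple(coef[j])
        ineqs.append((g, 1 - const[j]))  # a_j <= 1

    # initial box strictly containing the feasible region (free coords lie
    # in [0,1], so [-1, 2]^d works); box facets count as constraints during
    # the vertex rank test but can never be tight at a true vertex
    lo, hi = Fraction(-1), Fraction(2)
    verts: list[tuple[Fraction, ...]] = [tuple(v) for v in product((lo, hi), repeat=d)]
    constraints: list[tuple[tuple[Fraction, ...], Fraction]] = []
    for k in range(d):
        e = [Fraction(0)] * d
        e[k] = Fraction(1)
        constraints.append((tuple(e), hi))
        e = [Fraction(0)] * d
        e[k] = Fraction(-1)
        constraints.append((tuple(e), -lo))

    def dot(g, v):
        return sum(gi * vi for gi, vi in zip(g, v))

    for g, h in ineqs:
        vals = [dot(g, v) - h for v in verts]
        keep = [v for v, val in zip(verts, vals) if val <= 0]
        inside = [(v, val) for v, val in zip(verts, vals) if val < 0]
        outside = [(v, val) for v, val in zip(verts, vals) if val > 0]
        new: list[tuple[Fraction, ...]] = []
        seen = set(keep)
        all_constraints = constraints + [(g, h)]
        for vi, vali in inside:
            for vo, valo in outside:
                lam = vali / (vali - valo)  # in (0,1): the crossing point
                p = tuple(a + lam * (bq - a) for a, bq in zip(vi, vo))
                if p in seen:
                    continue
                seen.add(p)
                tight = [gg for gg, hh in all_constraints if dot(gg, p) == hh]
                if _rank(tight) == d:
                    new.append(p)
        verts = keep + new
        constraints.append((g, h))
        if not verts:
            break

    # map back to activation space, deduplicate, sort lexicographically
    out = set()
    for t in verts:
        a = tuple(const[j] + dot(coef[j], t) for j in range(n))
        out.add(a)
    if out:
        arr = np.array(sorted([[float(x) for x in a] for a in out]))
        # float-level dedup (exact dedup already done; keep the contract)
        if arr.shape[0] > 1:
            keep_rows = [0]
            for i in range(1, arr.shape[0]):
                if np.max(np.abs(arr[i] - arr[keep_rows[-1]])) > dedup_tol:
                    keep_rows.append(i)
            arr = arr[keep_rows]
    else:
        arr = np.empty((0, n))
    return VertexSet(arr, polytope.target_label, n_muscles=n)


def max_feasible_magnitude(
    action: ActionMatrix,
    direction: np.ndarray,
    zero_components: tuple[str, ...] = ("tz",),
) -> float:
    """Largest force magnitude c such that some a in [0,1]^n produces the
    wrench ``c * direction`` (embedded in the force plane) with all
    ``zero_components`` exactly zero.

    Solved as a linear program over (a, c); the box bounds on ``a`` make the
    program bounded, so an unbounded status indicates an invalid model.
    """
    labels = list(action.wrench_labels)
    for z in zero_components:
        if z not in labels:
            raise ConfigError(f"unknown wrench component {z!r}; model has {labels}")
    plane = [i for i, lab in enumerate(labels) if lab not in zero_components]
    zero = [i for i, lab in enumerate(labels) if lab in zero_components]
    u = np.atleast_1d(np.asarray(direction, dtype=float))
    if u.shape != (len(plane),):
        raise DimensionError(
            f"direction has {u.shape[0]} components for a {len(plane)}-dimensional force plane"
        )
    if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-9):
        raise ConfigError("direction must be a unit vector in the force plane")
    n = action.n_muscles
    A = action.matrix
    # variables x = (a_1..a_n, c); maximize c
    a_eq = np.zeros((len(plane) + len(zero), n + 1))
    a_eq[: len(plane), :n] = A[plane, :]
    a_eq[: len(plane), n] = -u
    a_eq[len(plane):, :n] = A[zero, :]
    b_eq = np.zeros(len(plane) + len(zero))
    c_obj = np.zeros(n + 1)
    c_obj[n] = -1.0
    res = linprog(
        c_obj,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0.0, 1.0)] * n + [(0.0, None)],
        method="highs",
    )
    if res.status == 3:  # pragma: no cover - impossible with box bounds
        raise MechSynergyError("feasibility LP reported unbounded; model is invalid")
    if not res.success:
        raise MechSynergyError(f"feasibility LP failed: {res.message}")
    return float(res.x[n])
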