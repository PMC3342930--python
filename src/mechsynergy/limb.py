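"""Limb model data structures and kinetostatic mappings.

A limb is described, at a posture, by a moment-arm matrix ``R`` (muscles x
joints, meters), an endpoint Jacobian ``J`` (endpoint DOFs x joints), and a
vector of maximum isometric forces ``F0`` (newtons).  These three objects
connect the spaces the analyses live in:

* joint rotation ``dq`` -> musculotendon stretch ``s = -R dq`` (positive
  stretch = lengthening; a positive moment arm shortens the muscle under a
  positive joint rotation, the standard biomechanics convention);
* endpoint displacement ``dx`` -> joint rotation ``dq = J^{-1} dx`` (the
  Jacobian is kept square and invertible by including the endpoint
  orientation among the endpoint DOFs);
* muscle activation ``a`` in [0,1]^n -> endpoint wrench ``w = A a`` with the
  action matrix ``A = J^{-T} R^T diag(F0)``.

Moment arms may be posture dependent: each entry ``r_ij`` can be a polynomial
in the angle of joint ``j``.  Stretch for a finite joint excursion then
integrates the moment arm along a straight joint-space path, which for
per-joint polynomials is exact (polynomial antiderivative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DimensionError, RankError, SingularityError, SizeCapError

__all__ = [
    "LimbModel",
    "ActionMatrix",
    "TensionProtocol",
    "planar_chain_jacobian",
    "compute_stretch",
    "endpoint_to_joint_delta",
    "action_matrix",
    "generate_tension_protocol",
    "estimate_action_matrix",
]

#: Default bound on the Jacobian condition number before a posture is
#: declared singular for analysis purposes.
DEFAULT_CONDITION_BOUND = 1e8

#: Refuse exhaustive on/off protocols above this many muscles (2^n rows).
PROTOCOL_MUSCLE_CAP = 20


def planar_chain_jacobian(
    link_lengths: np.ndarray, joint_angles: np.ndarray, orientation_row: bool = True
) -> np.ndarray:
    """Endpoint Jacobian of a planar serial chain.

    Joint angles are relative (each measured from the previous link); the
    endpoint is the tip of the last link.  Rows are (x, y[, orientation]);
    the orientation row is all ones (endpoint angle = sum of joint angles)
    and is what makes the Jacobian square and generically invertible for a
    3-joint limb.
    """
    L = np.asarray(link_lengths, dtype=float)
    q = np.asarray(joint_angles, dtype=float)
    if L.shape != q.shape:
        raise DimensionError(
            f"link_lengths has shape {L.shape} but joint_angles has shape {q.shape}"
        )
    theta = np.cumsum(q)  # absolute link angles
    n = len(q)
    J = np.zeros((3 if orientation_row else 2, n))
    for j in range(n):
        # distal links i >= j move when joint j rotates
        J[0, j] = -np.sum(L[j:] * np.sin(theta[j:]))
        J[1, j] = np.sum(L[j:] * np.cos(theta[j:]))
    if orientation_row:
        J[2, :] = 1.0
    return J


def _poly_eval(coeffs: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Evaluate per-entry moment-arm polynomials r_ij(q_j).

    ``coeffs`` has shape (n_muscles, n_joints, degree+1), lowest order first.
    """
    n_m, n_j, _ = coeffs.shape
    R = np.zeros((n_m, n_j))
    for j in range(n_j):
        R[:, j] = np.polynomial.polynomial.polyval(q[j], coeffs[:, j, :].T)
    return R


@dataclass
class LimbModel:
    """A musculoskeletal limb at (or parameterized around) a posture.

    Attributes
    ----------
    muscle_names, joint_names : lists of identifiers.
    moment_arms : (n_muscles, n_joints) array, meters, at ``posture``.
    jacobian : (n_endpoint_dofs, n_joints) array; translation rows in
        meters/radian, optional trailing orientation row dimensionless.
    max_forces : (n_muscles,) array, newtons, strictly positive.
    posture : (n_joints,) array of joint angles, radians.
    wrench_labels : one label per endpoint DOF (e.g. ["fx", "fy", "tz"]).
    moment_arm_coeffs : optional (n_muscles, n_joints, degree+1) polynomial
        coefficients making moment arms posture dependent.
    link_lengths : optional planar-chain link lengths, enabling the Jacobian
        to be re-derived at other postures via :func:`planar_chain_jacobian`.
    """

    muscle_names: list[str]
    joint_names: list[str]
    moment_arms: np.ndarray
    jacobian: np.ndarray
    max_forces: np.ndarray
    posture: np.ndarray
    wrench_labels: list[str] = field(default_factory=list)
    moment_arm_coeffs: np.ndarray | None = None
    link_lengths: np.ndarray | None = None
    condition_bound: float = DEFAULT_CONDITION_BOUND

    def __post_init__(self) -> None:
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, dtype=float))
        self.jacobian = np.atleast_2d(np.asarray(self.jacobian, dtype=float))
        self.max_forces = np.atleast_1d(np.asarray(self.max_forces, dtype=float))
        self.posture = np.atleast_1d(np.asarray(self.posture, dtype=float))
        if self.moment_arm_coeffs is not None:
            self.moment_arm_coeffs = np.asarray(self.moment_arm_coeffs, dtype=float)
        if self.link_lengths is not None:
            self.link_lengths = np.asarray(self.link_lengths, dtype=float)
        if not self.wrench_labels:
            n_e = self.jacobian.shape[0]
            self.wrench_labels = (["fx", "fy", "fz"][: n_e - 1] + ["tz"]) if n_e >= 3 else ["fx", "fy"][:n_e]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_m, n_j = self.moment_arms.shape
        if len(self.muscle_names) != n_m:
            raise DimensionError(
                f"{len(self.muscle_names)} muscle names for {n_m} moment-arm rows"
            )
        if len(self.joint_names) != n_j:
            raise DimensionError(
                f"{len(self.joint_names)} joint names for {n_j} moment-arm columns"
            )
        if n_m < n_j or n_j < 1:
            raise DimensionError(f"need n_muscles >= n_joints >= 1, got {n_m} x {n_j}")
        if self.max_forces.shape != (n_m,):
            raise DimensionError(
                f"max_forces has shape {self.max_forces.shape}, expected ({n_m},)"
            )
        if np.any(self.max_forces <= 0):
            raise SchemaLikeError("max_forces must be strictly positive")
        if not np.all(np.isfinite(self.moment_arms)):
            raise SchemaLikeError("moment_arms must be finite")
        if self.jacobian.shape[1] != n_j:
            raise DimensionError(
                f"jacobian has {self.jacobian.shape[1]} columns, expected {n_j}"
            )
        if self.posture.shape != (n_j,):
            raise DimensionError(
                f"posture has shape {self.posture.shape}, expected ({n_j},)"
            )
        if len(self.wrench_labels) != self.jacobian.shape[0]:
            raise DimensionError("one wrench label per endpoint DOF is required")
        if self.jacobian.shape[0] == self.jacobian.shape[1]:
            if np.linalg.matrix_rank(self.jacobian) < n_j:
                raise SingularityError(
                    "square Jacobian is rank deficient at the stored posture",
                    condition_number=float("inf"),
                )

    # -- derived properties ----------------------------------------------
    @property
    def n_muscles(self) -> int:
        return self.moment_arms.shape[0]

    @property
    def n_joints(self) -> int:
        return self.moment_arms.shape[1]

    @property
    def n_endpoint_dofs(self) -> int:
        return self.jacobian.shape[0]

    def moment_arms_at(self, posture: np.ndarray) -> np.ndarray:
        """Moment-arm matrix at an arbitrary posture (polynomials required
        for it to differ from the stored matrix)."""
        q = np.atleast_1d(np.asarray(posture, dtype=float))
        if q.shape != (self.n_joints,):
            raise DimensionError(f"posture has shape {q.shape}, expected ({self.n_joints},)")
        if self.moment_arm_coeffs is None:
            return self.moment_arms.copy()
        return _poly_eval(self.moment_arm_coeffs, q)

    def jacobian_at(self, posture: np.ndarray) -> np.ndarray:
        q = np.atleast_1d(np.asarray(posture, dtype=float))
        if self.link_lengths is None:
            return self.jacobian.copy()
        return planar_chain_jacobian(
            self.link_lengths, q, orientation_row=self.jacobian.shape[0] > 2
        )

    def at_posture(self, posture: np.ndarray) -> "LimbModel":
        """A snapshot of this limb at another posture.

        Moment arms are re-evaluated from their polynomials (if any) and the
        Jacobian re-derived from the link geometry (if known); otherwise the
        stored matrices carry over unchanged.
        """
        q = np.atleast_1d(np.asarray(posture, dtype=float))
        return replace(
            self,
            moment_arms=self.moment_arms_at(q),
            jacobian=self.jacobian_at(q),
            posture=q,
        )


class SchemaLikeError(ValueError):
    """Invariant violation in a limb model (subclass of ValueError so that
    direct construction and file validation share one failure type)."""


@dataclass
class ActionMatrix:
    """Linear map from muscle activation (or tension) to endpoint wrench.

    Column ``i`` is the endpoint wrench produced by muscle ``i`` at unit
    input; ``matrix`` has shape (n_wrench_dims, n_muscles).
    """

    matrix: np.ndarray
    wrench_labels: list[str]
    muscle_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.isfinite(self.matrix)):
            raise SchemaLikeError("action matrix must be finite")
        if len(self.wrench_labels) != self.matrix.shape[0]:
            raise DimensionError("one wrench label per action-matrix row is required")
        if not self.muscle_names:
            self.muscle_names = [f"m{i}" for i in range(self.matrix.shape[1])]

    @property
    def n_muscles(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TensionProtocol:
    """An exhaustive on/off tendon-tension protocol.

    ``patterns`` is (n_patterns, n_muscles) in newtons, every entry equal to
    ``active_level`` or ``inactive_level``.  Ordering is binary counting with
    muscle 0 as the least significant bit, so row ``k`` activates exactly the
    muscles whose bit is set in ``k``.
    """

    patterns: np.ndarray
    active_level: float
    inactive_level: float

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        levels = {self.active_level, self.inactive_level}
        if not np.all(np.isin(self.patterns, sorted(levels))):
            raise SchemaLikeError("every protocol entry must equal active_level or inactive_level")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.patterns.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_stretch(
    model: LimbModel, joint_delta: np.ndarray, integrate: bool | None = None
) -> np.ndarray:
    """Musculotendon stretch (m, positive = lengthening) for a joint excursion.

    For constant moment arms this is the linear map ``s = -R dq``.  For
    posture-dependent (polynomial) moment arms, ``integrate=True`` (the
    default when polynomials are present) computes the exact line integral
    of ``-r_ij`` along the straight path from ``model.posture`` to
    ``model.posture + joint_delta``; ``integrate=False`` forces the
    linearization at the stored posture (the convention for small
    perturbation analyses).
    """
    dq = np.atleast_1d(np.asarray(joint_delta, dtype=float))
    if dq.shape != (model.n_joints,):
        raise DimensionError(
            f"joint_delta has shape {dq.shape}, expected ({model.n_joints},)"
        )
    if not np.all(np.isfinite(dq)):
        raise DimensionError("joint_delta must be finite")
    if integrate is None:
        integrate = model.moment_arm_coeffs is not None
    if not integrate or model.moment_arm_coeffs is None:
        return -model.moment_arms @ dq
    q0 = model.posture
    q1 = q0 + dq
    s = np.zeros(model.n_muscles)
    for j in range(model.n_joints):
        # antiderivative of r_ij(q_j), evaluated between q0_j and q1_j
        anti = np.polynomial.polynomial.polyint(model.moment_arm_coeffs[:, j, :].T)
        s -= np.polynomial.polynomial.polyval(q1[j], anti) - np.polynomial.polynomial.polyval(
            q0[j], anti
        )
    return s


def endpoint_to_joint_delta(model: LimbModel, endpoint_delta: np.ndarray) -> np.ndarray:
    """Invert the Jacobian: joint excursion producing a small endpoint
    displacement (orientation component included; set it to 0 to hold the
    endpoint orientation fixed)."""
    dx = np.atleast_1d(np.asarray(endpoint_delta, dtype=float))
    J = model.jacobian
    if J.shape[0] != J.shape[1]:
        raise SingularityError(
            f"Jacobian is {J.shape[0]}x{J.shape[1]}, not square; endpoint inversion needs "
            "the orientation DOF included"
        )
    if dx.shape != (J.shape[0],):
        raise DimensionError(f"endpoint_delta has shape {dx.shape}, expected ({J.shape[0]},)")
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > model.condition_bound:
        raise SingularityError(
            f"Jacobian condition number {cond:.3e} exceeds bound {model.condition_bound:.3e}",
            condition_number=float(cond),
        )
    return np.linalg.solve(J, dx)


def action_matrix(model: LimbModel) -> ActionMatrix:
    """Endpoint wrench per unit activation: ``A = J^{-T} R^T diag(F0)``.

    Column i is the wrench of muscle i at activation 1 (tension F0_i).
    """
    J = model.jacobian
    if J.shape[0] != J.shape[1]:
        raise SingularityError("action matrix requires a square (invertible) Jacobian")
    cond = np.linalg.cond(J)
    if not np.isfinite(cond) or cond > model.condition_bound:
        raise SingularityError(
            f"Jacobian condition number {cond:.3e} exceeds bound {model.condition_bound:.3e}",
            condition_number=float(cond),
        )
    A = np.linalg.solve(J.T, model.moment_arms.T * model.max_forces[np.newaxis, :])
    return ActionMatrix(A, list(model.wrench_labels), list(model.muscle_names))


def generate_tension_protocol(
    n_muscles: int,
    active_level: float = 10.0,
    inactive_level: float = 0.0,
    cap: int = PROTOCOL_MUSCLE_CAP,
) -> TensionProtocol:
    """All 2^n on/off tension patterns, binary counting, muscle 0 = LSB."""
    if n_muscles < 1:
        raise ConfigError("n_muscles must be >= 1")
    if active_level == inactive_level:
        raise ConfigError("active_level must differ from inactive_level")
    if n_muscles > cap:
        raise SizeCapError(
            f"refusing exhaustive protocol for {n_muscles} muscles "
            f"(2^{n_muscles} patterns exceeds the cap of {cap} muscles)"
        )
    k = np.arange(2**n_muscles)
    bits = (k[:, None] >> np.arange(n_muscles)[None, :]) & 1
    patterns = np.where(bits == 1, active_level, inactive_level).astype(float)
    return TensionProtocol(patterns, active_level, inactive_level)


def estimate_action_matrix(
    protocol: TensionProtocol,
    wrenches: np.ndarray,
    wrench_labels: list[str] | None = None,
    muscle_names: list[str] | None = None,
) -> ActionMatrix:
    """Least-squares action matrix from tendon tensions and measured wrenches.

    Regresses each wrench component on the applied tensions with an intercept
    (the rig's baseline wrench), then discards the intercept; the returned
    matrix maps unit tension to wrench.
    """
    W = np.atleast_2d(np.asarray(wrenches, dtype=float))
    if W.shape[0] != protocol.n_patterns:
        raise DimensionError(
            f"{W.shape[0]} wrench rows for {protocol.n_patterns} protocol patterns"
        )
    if protocol.n_patterns < protocol.n_muscles:
        raise RankError("need at least as many patterns as muscles")
    X = np.column_stack([protocol.patterns, np.ones(protocol.n_patterns)])
    if np.linalg.matrix_rank(protocol.patterns) < protocol.n_muscles:
        raise RankError("tension protocol design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, W, rcond=None)
    A = coef[:-1, :].T  # (n_wrench_dims, n_muscles); last row was the intercept
    labels = wrench_labels or [f"w{i}" for i in range(A.shape[0])]
    return ActionMatrix(A, labels, muscle_names or [f"m{i}" for i in range(A.shape[1])])
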