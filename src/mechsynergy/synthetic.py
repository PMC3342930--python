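"""Synthetic limb models and endpoint movement sets.

Every input the two analyses need can be generated here, so the full
pipelines run without any external downloads:

* a 3-muscle / 2-joint schematic limb (the minimal system in which the
  length-change subspace argument can be drawn);
* a 7-muscle planar index-finger-like limb (FDP, FDS, EI, EDC, LUM, FDI,
  FPI) with a 3-component endpoint wrench (two forces and a torque);
* a 14-muscle-group sagittal-plane leg (hip, knee, ankle) with link lengths
  scaled from stature;
* random limb models, random planar workspace movements, and equally spaced
  perturbation direction sets.

All moment arms and maximum forces for the named models are documented
stand-ins at physiologically plausible magnitudes; none are measurements.
The analyses anchored on these models test structural properties (ranks,
dimensionality bounds, feasibility), not specific parameter values, and
every default can be overridden from a model file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DimensionError
from .limb import LimbModel, planar_chain_jacobian

__all__ = [
    "MovementSet",
    "make_schematic_limb",
    "make_finger_like",
    "make_leg_like",
    "random_model",
    "random_workspace_movements",
    "perturbation_directions",
    "group_muscles",
    "synthetic_detailed_leg",
]


@dataclass
class MovementSet:
    """A set of small endpoint displacements around a reference posture.

    ``displacements`` is (n_samples, n_endpoint_dofs): translation columns in
    meters, an orientation column (if present) in radians and identically
    zero whenever the endpoint orientation is held fixed.
    """

    displacements: np.ndarray
    reference_posture: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.displacements = np.atleast_2d(np.asarray(self.displacements, dtype=float))
        if not np.all(np.isfinite(self.displacements)):
            raise DimensionError("displacements must be finite")

    @property
    def n_samples(self) -> int:
        return self.displacements.shape[0]


# ---------------------------------------------------------------------------
# named models
# ---------------------------------------------------------------------------

def make_schematic_limb() -> LimbModel:
    """The minimal 3-muscle, 2-joint planar limb.

    Muscle 1 spans only the first joint, muscle 2 only the second, and
    muscle 3 is a biarticular antagonist to both, so the moment-arm matrix
    has rank 2 and no two muscles are mechanically identical.  The endpoint
    is the tip of a 2-link planar chain (2 translational DOFs, no
    orientation row, so the Jacobian is square 2x2).
    """
    posture = np.array([0.7, 1.1])
    link_lengths = np.array([0.30, 0.28])
    return LimbModel(
        muscle_names=["mono1", "mono2", "bi12"],
        joint_names=["j1", "j2"],
        moment_arms=np.array(
            [
                [0.025, 0.000],
                [0.000, 0.020],
                [-0.018, -0.015],
            ]
        ),
        jacobian=planar_chain_jacobian(link_lengths, posture, orientation_row=False),
        max_forces=np.array([300.0, 250.0, 400.0]),
        posture=posture,
        wrench_labels=["fx", "fy"],
        link_lengths=link_lengths,
    )


#: Finger moment arms (m) per joint [MCP, PIP, DIP]; flexion positive.
_FINGER_MOMENT_ARMS = {
    "FDP": [0.0110, 0.0079, 0.0041],
    "FDS": [0.0120, 0.0087, 0.0000],
    "EI": [-0.0089, -0.0020, -0.0010],
    "EDC": [-0.0080, -0.0060, -0.0030],
    "LUM": [0.0065, -0.0040, -0.0025],
    "FDI": [0.0075, 0.0030, 0.0000],
    "FPI": [0.0060, -0.0010, 0.0000],
}
#: Stand-in tendon strengths (N), scaled so the feasible force set admits
#: several 1 N force levels in every planar direction at both posture
#: presets (the muscle torque vectors positively span joint-torque space).
_FINGER_MAX_FORCES = {
    "FDP": 250.0,
    "FDS": 200.0,
    "EI": 90.0,
    "EDC": 110.0,
    "LUM": 30.0,
    "FDI": 180.0,
    "FPI": 120.0,
}
#: Two documented posture presets (radians, flexion positive).
FINGER_POSTURES = {
    "extended": np.array([0.25, 0.20, 0.10]),
    "flexed": np.array([0.80, 0.70, 0.35]),
}


def make_finger_like(posture: str | np.ndarray = "extended") -> LimbModel:
    """A 7-muscle planar index-finger-like limb.

    Three flexion joints (MCP, PIP, DIP) move the fingertip in the
    palmar-proximal plane; the endpoint wrench has two force components and
    one torque, making the Jacobian square.  The seven muscles carry the
    standard index-finger abbreviations.  Moment arms get a mild linear
    posture dependence (flexor arms grow slightly with flexion) so that
    cross-posture analyses are non-trivial.
    """
    if isinstance(posture, str):
        try:
            q = FINGER_POSTURES[posture].copy()
        except KeyError:
            raise ConfigError(
                f"unknown finger posture preset {posture!r}; options: {sorted(FINGER_POSTURES)}"
            ) from None
    else:
        q = np.atleast_1d(np.asarray(posture, dtype=float))
    names = list(_FINGER_MOMENT_ARMS)
    R0 = np.array([_FINGER_MOMENT_ARMS[m] for m in names])
    # linear posture dependence anchored at zero flexion: the arm grows by
    # 12% of its nominal value per radian of that joint's flexion
    slopes = 0.12 * R0
    coeffs = np.stack([R0, slopes], axis=-1)
    link_lengths = np.array([0.045, 0.027, 0.018])
    return LimbModel(
        muscle_names=names,
        joint_names=["mcp", "pip", "dip"],
        moment_arms=R0 * (1.0 + 0.12 * q[np.newaxis, :]),
        jacobian=planar_chain_jacobian(link_lengths, q, orientation_row=True),
        max_forces=np.array([_FINGER_MAX_FORCES[m] for m in names]),
        posture=q,
        wrench_labels=["fx", "fy", "tz"],
        moment_arm_coeffs=coeffs,
        link_lengths=link_lengths,
    )


#: Leg muscle groups: moment arms (m) per joint [hip, knee, ankle].
#: Sign convention: hip flexion, knee flexion, ankle dorsiflexion positive.
_LEG_MOMENT_ARMS = {
    "gastroc_med": [0.000, 0.020, -0.048],
    "gastroc_lat": [0.000, 0.018, -0.046],
    "soleus": [0.000, 0.000, -0.049],
    "tibpost": [0.000, 0.000, -0.014],
    "perbrev": [0.000, 0.000, -0.012],
    "tibant": [0.000, 0.000, 0.040],
    "hamstring": [-0.060, 0.035, 0.000],
    "bfsh": [0.000, 0.030, 0.000],
    "rectfem": [0.045, -0.045, 0.000],
    "glmed/min": [-0.015, 0.000, 0.000],
    "addlong": [0.020, 0.000, 0.000],
    "iliacus": [0.045, 0.000, 0.000],
    "tensfl": [0.030, 0.000, 0.000],
    "glmax": [-0.060, 0.000, 0.000],
}
_LEG_MAX_FORCES = {
    "gastroc_med": 1100.0,
    "gastroc_lat": 600.0,
    "soleus": 2800.0,
    "tibpost": 1300.0,
    "perbrev": 350.0,
    "tibant": 900.0,
    "hamstring": 2600.0,
    "bfsh": 800.0,
    "rectfem": 1200.0,
    "glmed/min": 2700.0,
    "addlong": 600.0,
    "iliacus": 1200.0,
    "tensfl": 150.0,
    "glmax": 1900.0,
}

#: Segment lengths as fractions of stature (thigh, shank, foot lever),
#: standard anthropometric proportions; configurable via the argument.
LEG_SEGMENT_FRACTIONS = (0.245, 0.246, 0.152)

#: Default sagittal leg posture (hip, knee, ankle; radians). A mildly
#: crouched stance, away from the straight-leg singularity.
LEG_POSTURE = np.array([-1.2, 0.8, -0.9])


def make_leg_like(
    stature_m: float = 1.70,
    posture: np.ndarray | None = None,
    segment_fractions: tuple[float, float, float] = LEG_SEGMENT_FRACTIONS,
    detailed: tuple[list[str], np.ndarray, np.ndarray, dict[str, list[int]]] | None = None,
) -> LimbModel:
    """A 14-muscle-group, 3-joint sagittal-plane leg.

    The endpoint is the foot; its state includes the foot orientation, so
    the 3x3 Jacobian is invertible away from the straight-leg singularity.
    Muscle groups follow the standard lower-limb grouping, with the
    gastrocnemius split into its medial and lateral heads to reach 14.

    When ``detailed`` is given as ``(names, moment_arms, max_forces,
    groups)`` for an externally supplied many-muscle table (e.g. extracted
    from a published lower-extremity model), group moment arms are the
    max-force-weighted averages of the member muscles and group forces their
    sums, which preserves the torque-generating capacity about every joint
    exactly.
    """
    if stature_m <= 0:
        raise ConfigError("stature must be positive")
    q = LEG_POSTURE.copy() if posture is None else np.atleast_1d(np.asarray(posture, float))
    link_lengths = stature_m * np.asarray(segment_fractions, dtype=float)

    if detailed is None:
        names = list(_LEG_MOMENT_ARMS)
        R0 = np.array([_LEG_MOMENT_ARMS[m] for m in names])
        F0 = np.array([_LEG_MAX_FORCES[m] for m in names])
    else:
        src_names, src_R, src_F, groups = detailed
        names, R0, F0 = group_muscles(np.asarray(src_R, float), np.asarray(src_F, float), groups)

    # mild linear posture dependence anchored at the upright zero posture
    # (10% of the nominal arm per radian)
    slopes = 0.10 * R0
    coeffs = np.stack([R0, slopes], axis=-1)
    return LimbModel(
        muscle_names=names,
        joint_names=["hip", "knee", "ankle"],
        moment_arms=R0 * (1.0 + 0.10 * q[np.newaxis, :]),
        jacobian=planar_chain_jacobian(link_lengths, q, orientation_row=True),
        max_forces=F0,
        posture=q,
        wrench_labels=["fx", "fy", "tz"],
        moment_arm_coeffs=coeffs,
        link_lengths=link_lengths,
    )


def group_muscles(
    moment_arms: np.ndarray,
    max_forces: np.ndarray,
    groups: dict[str, list[int]],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Force-weighted muscle grouping.

    Each group's moment arm is the member arms averaged with their maximum
    isometric forces as weights, and its maximum force is the member sum,
    so ``r_gj * F_g == sum_i r_ij * F_i``: per-joint torque capacity is
    conserved exactly.
    """
    R = np.atleast_2d(np.asarray(moment_arms, dtype=float))
    F = np.atleast_1d(np.asarray(max_forces, dtype=float))
    if R.shape[0] != F.shape[0]:
        raise DimensionError("moment_arms rows and max_forces length must match")
    names, R_rows, F_out = [], [], []
    for name, idx in groups.items():
        idx = list(idx)
        if not idx:
            raise ConfigError(f"group {name!r} is empty")
        w = F[idx]
        names.append(name)
        F_out.append(w.sum())
        R_rows.append((R[idx] * w[:, None]).sum(axis=0) / w.sum())
    return names, np.array(R_rows), np.array(F_out)


def synthetic_detailed_leg(
    seed: int = 0, n_muscles: int = 44
) -> tuple[list[str], np.ndarray, np.ndarray, dict[str, list[int]]]:
    """A synthetic many-muscle leg table (stand-in, not a published model).

    Splits each of the 14 default muscle groups into several constituent
    muscles whose moment arms scatter around the group arm and whose maximum
    forces partition the group force.  Useful for exercising the grouping
    machinery and the many-muscle feedback pipeline without shipping any
    third-party model data.  Returns ``(names, moment_arms, max_forces,
    groups)`` suitable for ``make_leg_like(detailed=...)``.
    """
    rng = np.random.default_rng(seed)
    base_names = list(_LEG_MOMENT_ARMS)
    n_groups = len(base_names)
    if n_muscles < n_groups:
        raise ConfigError(f"need at least {n_groups} muscles")
    # distribute muscle counts over groups: start at 1 each, then spread
    counts = np.ones(n_groups, dtype=int)
    for _ in range(n_muscles - n_groups):
        counts[rng.integers(n_groups)] += 1
    names: list[str] = []
    rows: list[np.ndarray] = []
    forces: list[float] = []
    groups: dict[str, list[int]] = {}
    for g, gname in enumerate(base_names):
        R_g = np.array(_LEG_MOMENT_ARMS[gname])
        F_g = _LEG_MAX_FORCES[gname]
        shares = rng.dirichlet(np.full(counts[g], 4.0))
        groups[gname] = []
        for k in range(counts[g]):
            groups[gname].append(len(names))
            names.append(f"{gname}.{k}")
            rows.append(R_g * (1.0 + 0.15 * rng.standard_normal(R_g.shape)))
            forces.append(F_g * shares[k])
    return names, np.array(rows), np.array(forces), groups


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------

def random_model(
    n_muscles: int,
    n_joints: int,
    seed: int,
    posture_dependent: bool = False,
) -> LimbModel:
    """A reproducible random limb model.

    The moment-arm matrix has full column rank and every joint is spanned by
    at least one positive and one negative moment arm, so antagonism exists
    and feasible activation sets are nondegenerate.  The Jacobian is square
    and well conditioned by construction.
    """
    if not n_muscles > n_joints >= 1:
        raise ConfigError(f"need n_muscles > n_joints >= 1, got {n_muscles}, {n_joints}")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        R = 0.03 * rng.standard_normal((n_muscles, n_joints))
        has_antagonism = all(
            (R[:, j] > 0).any() and (R[:, j] < 0).any() for j in range(n_joints)
        )
        if has_antagonism and np.linalg.matrix_rank(R) == n_joints:
            break
    else:  # pragma: no cover - probability ~0
        raise ConfigError("could not generate a full-rank antagonistic moment-arm matrix")
    # well-conditioned random Jacobian: random rotation times spread scales
    Q, _ = np.linalg.qr(rng.standard_normal((n_joints, n_joints)))
    J = Q * rng.uniform(0.2, 0.5, size=n_joints)[np.newaxis, :]
    labels = (
        ["fx", "fy"] if n_joints == 2 else (["fx", "fy", "tz"] if n_joints == 3 else [f"w{i}" for i in range(n_joints)])
    )
    coeffs = None
    if posture_dependent:
        slopes = 0.004 * rng.standard_normal(R.shape)
        coeffs = np.stack([R, slopes], axis=-1)  # posture stored at the origin
    return LimbModel(
        muscle_names=[f"m{i}" for i in range(n_muscles)],
        joint_names=[f"j{j}" for j in range(n_joints)],
        moment_arms=R,
        jacobian=J,
        max_forces=rng.uniform(50.0, 500.0, size=n_muscles),
        posture=np.zeros(n_joints),
        wrench_labels=labels,
        moment_arm_coeffs=coeffs,
    )


def random_workspace_movements(
    model: LimbModel,
    n_samples: int,
    radius: float | None = None,
    seed: int = 0,
    mode: str = "disc",
) -> MovementSet:
    """Random planar endpoint displacements around the reference posture.

    Emulates moving the endpoint at random until the planar workspace around
    the starting posture is filled.  ``disc`` (default) draws uniformly from
    the disc of the given radius; ``walk`` takes a reflected random walk
    inside the same disc.  The default radius is 10% of the limb length
    (linearization regime); any orientation component is held at zero.
    """
    if radius is None:
        scale = float(np.sum(model.link_lengths)) if model.link_lengths is not None else 1.0
        radius = 0.10 * scale
    if radius <= 0:
        raise ConfigError("radius must be positive")
    rng = np.random.default_rng(seed)
    if mode == "disc":
        pts = np.empty((0, 2))
        while pts.shape[0] < n_samples:
            cand = rng.uniform(-radius, radius, size=(2 * n_samples + 8, 2))
            cand = cand[np.einsum("ij,ij->i", cand, cand) <= radius**2]
            pts = np.vstack([pts, cand])
        pts = pts[:n_samples]
    elif mode == "walk":
        steps = rng.normal(scale=radius / 10.0, size=(n_samples, 2))
        pts = np.cumsum(steps, axis=0)
        norms = np.linalg.norm(pts, axis=1)
        over = norms > radius  # reflect back inside the disc
        pts[over] *= ((2 * radius - norms[over]).clip(min=0.0) / norms[over])[:, None]
    else:
        raise ConfigError(f"unknown movement mode {mode!r}; options: disc, walk")
    disp = np.zeros((n_samples, model.n_endpoint_dofs))
    disp[:, :2] = pts
    return MovementSet(disp, reference_posture=model.posture.copy(), seed=seed)


def perturbation_directions(
    k: int, magnitude: float, n_endpoint_dofs: int = 3
) -> MovementSet:
    """k endpoint perturbations at equally spaced planar angles.

    Unit vectors at angles ``2*pi*j/k`` starting at 0, scaled by
    ``magnitude``; the orientation component (and any extra endpoint DOFs)
    are zero, i.e. the endpoint orientation is held fixed.
    """
    if k < 2:
        raise ConfigError("need at least 2 perturbation directions")
    if n_endpoint_dofs < 2:
        raise ConfigError("perturbations are planar; need n_endpoint_dofs >= 2")
    ang = 2.0 * np.pi * np.arange(k) / k
    disp = np.zeros((k, n_endpoint_dofs))
    disp[:, 0] = magnitude * np.cos(ang)
    disp[:, 1] = magnitude * np.sin(ang)
    return MovementSet(disp)
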