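"""Feedback-related synergies: stretch-evoked simulated EMG.

The thought experiment: no descending controller groups muscles; instead
each muscle independently resists being lengthened.  A small endpoint
perturbation ``dx`` induces joint rotations ``dq = J^{-1} dx`` and
musculotendon stretches ``s = -R dq``; a muscle produces simulated EMG only
when stretched, ``EMG_i = G * max(0, s_i)`` with one shared gain ``G``
(alternative monotone stretch-to-EMG transforms give the same active/silent
pattern and similar dimensionality).  Because the stretches across all
planar perturbation directions live in a subspace of rank <= n_joints
(spanned by the moment arms grouped by joint), the simulated EMG is
low-dimensional without any neural coupling among muscles — and a PCA basis
fitted at one posture can reconstruct EMG at distant postures, i.e. these
"synergies" also generalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DimensionError, SingularityError
from .limb import LimbModel, compute_stretch, endpoint_to_joint_delta
from .pca import (
    VAF_GENERALIZATION_THRESHOLD,
    PcaBasis,
    VafReport,
    n_components_for_generalization,
    pca_fit,
    reconstruct_vaf,
)
from .synthetic import MovementSet

__all__ = [
    "EmgTransform",
    "EmgMatrix",
    "stretch_matrix",
    "simulate_emg",
    "generalization_map",
    "FeedbackSynergy",
    "FeedbackSynergyResults",
]

_TRANSFORM_KINDS = ("rectified_linear", "linear", "exponential", "sigmoidal")


@dataclass(frozen=True)
class EmgTransform:
    """Monotone map from musculotendon stretch (m) to simulated EMG.

    The gain is shared across muscles (it rescales the EMG cloud without
    changing its shape, hence never changes dimensionality).  All kinds
    except the unrectified ``linear`` control output exactly 0 for
    non-positive stretch:

    - ``rectified_linear``: ``G * max(0, s)`` (the default thought experiment);
    - ``linear``: ``G * s``, signed — a control for studying the
      pre-rectification subspace;
    - ``exponential``: ``G * (exp(rate * max(0, s)) - 1)``;
    - ``sigmoidal``: logistic in stretch, shifted to pass through 0 at
      ``s = 0`` and clamped to 0 for ``s <= 0``.
    """

    kind: str = "rectified_linear"
    gain: float = 1.0
    rate: float = 100.0  # exponential steepness, 1/m
    midpoint: float = 0.005  # sigmoid midpoint, m
    slope: float = 500.0  # sigmoid steepness, 1/m

    def __post_init__(self) -> None:
        if self.kind not in _TRANSFORM_KINDS:
            raise ConfigError(
                f"unknown transform kind {self.kind!r}; options: {_TRANSFORM_KINDS}"
            )
        if self.gain < 0:
            raise ConfigError("gain must be nonnegative")

    def apply(self, stretch: np.ndarray) -> np.ndarray:
        s = np.asarray(stretch, dtype=float)
        if self.kind == "linear":
            return self.gain * s
        sp = np.maximum(0.0, s)
        if self.kind == "rectified_linear":
            return self.gain * sp
        if self.kind == "exponential":
            return self.gain * np.expm1(self.rate * sp)
        # sigmoidal, shifted so the output is 0 at zero stretch
        def logistic(x):
            return 1.0 / (1.0 + np.exp(-x))

        base = logistic(-self.slope * self.midpoint)
        out = logistic(self.slope * (sp - self.midpoint)) - base
        return self.gain * np.where(s > 0, out, 0.0)


@dataclass
class EmgMatrix:
    """Simulated activations, muscles x conditions.

    Nonnegative for rectified transforms; the signed ``linear`` control
    transform sets ``allow_negative``.
    """

    values: np.ndarray
    condition_labels: list[str] = field(default_factory=list)
    muscle_names: list[str] = field(default_factory=list)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise DimensionError("EMG values must be finite")
        if not self.allow_negative and np.any(self.values < 0):
            raise DimensionError("EMG values must be nonnegative")
        if not self.condition_labels:
            self.condition_labels = [f"c{i}" for i in range(self.values.shape[1])]
        if not self.muscle_names:
            self.muscle_names = [f"m{i}" for i in range(self.values.shape[0])]

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


def stretch_matrix(model: LimbModel, movements: MovementSet) -> np.ndarray:
    """Pre-rectification stretches, muscles x conditions.

    The perturbation analysis is linearized at the reference posture
    (``s = -R J^{-1} dx`` per condition, moment arms held at their posture
    values), so over planar endpoint displacements this matrix has rank at
    most min(n_joints, movement dimension) *exactly* — the mechanical
    constraint at the heart of the feedback argument.
    """
    X = movements.displacements
    if X.shape[1] != model.n_endpoint_dofs:
        raise DimensionError(
            f"movements have {X.shape[1]} endpoint DOFs, model has {model.n_endpoint_dofs}"
        )
    S = np.empty((model.n_muscles, X.shape[0]))
    for c in range(X.shape[0]):
        dq = endpoint_to_joint_delta(model, X[c])
        S[:, c] = compute_stretch(model, dq, integrate=False)
    return S


def simulate_emg(
    model: LimbModel, movements: MovementSet, transform: EmgTransform | None = None
) -> EmgMatrix:
    """Simulated EMG for a set of endpoint displacements.

    Per condition: ``dq = J^{-1} dx``, ``s = -R dq`` (path-integrated when
    moment arms are posture dependent), ``EMG = transform(s)``.
    """
    transform = transform or EmgTransform()
    S = stretch_matrix(model, movements)
    return EmgMatrix(
        transform.apply(S),
        condition_labels=[f"c{i}" for i in range(S.shape[1])],
        muscle_names=list(model.muscle_names),
        allow_negative=transform.kind == "linear",
    )


def generalization_map(
    model: LimbModel,
    reference_posture: np.ndarray,
    test_postures: list[np.ndarray],
    k: int,
    transform: EmgTransform | None = None,
    movements: MovementSet | None = None,
    threshold: float = VAF_GENERALIZATION_THRESHOLD,
    centered: bool = True,
    use_test_mean: bool = False,
) -> tuple[list[VafReport], list[int]]:
    """Cross-posture synergy generalization.

    Fits a PCA basis to simulated EMG at the reference posture, then asks,
    for every test posture (with its own moment arms and Jacobian), whether
    the first ``k`` reference components reconstruct that posture's EMG with
    VAF > threshold in every muscle.  Postures with a singular or
    ill-conditioned Jacobian are recorded as excluded, not fatal.

    Returns ``(reports, excluded_indices)``; ``reports`` has one entry per
    non-excluded test posture, in input order.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    transform = transform or EmgTransform()
    if movements is None:
        raise ConfigError("a MovementSet (e.g. perturbation_directions) is required")
    ref = model.at_posture(np.asarray(reference_posture, dtype=float))
    ref_emg = simulate_emg(ref, movements, transform)
    basis = pca_fit(ref_emg, centered=centered)
    reports: list[VafReport] = []
    excluded: list[int] = []
    for i, q in enumerate(test_postures):
        try:
            test = model.at_posture(np.asarray(q, dtype=float))
            emg = simulate_emg(test, movements, transform)
        except SingularityError:
            excluded.append(i)
            continue
        b = basis
        if use_test_mean:
            b = replace(basis, mean=emg.values.mean(axis=1))
        reports.append(
            reconstruct_vaf(b, k, emg, threshold=threshold, muscle_names=emg.muscle_names)
        )
    return reports, excluded


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class FeedbackSynergy:
    """Feedback-related synergy analysis of one limb model.

    Parameters
    ----------
    limb : LimbModel
        The limb at its reference posture.
    movements : MovementSet
        Endpoint perturbations (e.g. ``perturbation_directions(16, 0.10)``).
    transform : EmgTransform, optional
        Stretch-to-EMG map; rectified linear with unit gain by default.
    centered : bool
        Whether the dimensionality PCA removes the mean EMG (default True).
    """

    def __init__(
        self,
        limb: LimbModel,
        movements: MovementSet,
        transform: EmgTransform | None = None,
        centered: bool = True,
    ):
        if movements.displacements.shape[1] != limb.n_endpoint_dofs:
            raise DimensionError(
                "movement endpoint dimension does not match the limb model"
            )
        self.limb = limb
        self.movements = movements
        self.transform = transform or EmgTransform()
        self.centered = centered

    def fit(self, threshold: float = VAF_GENERALIZATION_THRESHOLD) -> "FeedbackSynergyResults":
        emg = simulate_emg(self.limb, self.movements, self.transform)
        basis = pca_fit(emg, centered=self.centered)
        cum = basis.cumulative_variance()
        above = np.nonzero(cum > threshold)[0]
        n_comp = int(above[0]) + 1 if len(above) else basis.n_components
        return FeedbackSynergyResults(self, emg, basis, threshold, n_comp)


@dataclass
class FeedbackSynergyResults:
    """Fitted feedback-synergy dimensionality and generalization tools.

    ``n_components`` counts components by the global cumulative-variance
    rule; ``n_components_generalizing`` is the (usually larger) count needed
    for the per-muscle VAF criterion at the reference posture itself, and is
    the default basis size for cross-posture generalization.
    """

    model: FeedbackSynergy
    emg: EmgMatrix
    basis: PcaBasis
    threshold: float
    n_components: int

    def cumulative_variance(self) -> np.ndarray:
        return self.basis.cumulative_variance()

    @property
    def n_components_generalizing(self) -> int:
        return n_components_for_generalization(self.basis, self.emg, self.threshold)

    def reconstruct_self(self, k: int | None = None) -> VafReport:
        return reconstruct_vaf(
            self.basis,
            k or self.n_components,
            self.emg,
            threshold=self.threshold,
            muscle_names=self.emg.muscle_names,
        )

    def generalize(self, test_posture: np.ndarray, k: int | None = None,
                   use_test_mean: bool = False) -> VafReport:
        """Reconstruct EMG simulated at another posture with this basis."""
        test = self.model.limb.at_posture(np.asarray(test_posture, dtype=float))
        emg = simulate_emg(test, self.model.movements, self.model.transform)
        b = self.basis
        if use_test_mean:
            b = replace(self.basis, mean=emg.values.mean(axis=1))
        return reconstruct_vaf(
            b, k or self.n_components_generalizing, emg,
            threshold=self.threshold, muscle_names=emg.muscle_names,
        )

    def generalization_map(
        self, test_postures: list[np.ndarray], k: int | None = None,
        use_test_mean: bool = False,
    ) -> tuple[list[VafReport], list[int]]:
        return generalization_map(
            self.model.limb,
            self.model.limb.posture,
            test_postures,
            k or self.n_components_generalizing,
            transform=self.model.transform,
            movements=self.model.movements,
            threshold=self.threshold,
            centered=self.model.centered,
            use_test_mean=use_test_mean,
        )

    def summary(self) -> str:
        limb = self.model.limb
        cum = self.cumulative_variance()
        lines = [
            "Feedback-related synergy analysis",
            "=" * 49,
            f"muscles:              {limb.n_muscles}",
            f"perturbations:        {self.emg.n_conditions}",
            f"transform:            {self.model.transform.kind} (gain {self.model.transform.gain:g})",
            f"PCA centering:        {self.model.centered}",
            f"components for >{self.threshold:.0%} EMG variance: {self.n_components}",
            "",
            "  PC   var ratio   cumulative",
        ]
        for i, (r, c) in enumerate(zip(self.basis.explained_variance_ratios, cum)):
            lines.append(f"  {i + 1:>2}   {r:9.4f}   {c:10.4f}")
            if c > 0.999 and i >= self.n_components:
                break
        return "\n".join(lines)
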