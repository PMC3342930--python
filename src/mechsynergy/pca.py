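"""Principal components and variance-accounted-for (VAF) computations.

Both analyses quantify dimensionality the same way: PCA on a cloud of
points in muscle space (one point per condition — a movement direction, or
a vertex of an activation solution set), followed by asking how many
components exceed a cumulative explained-variance threshold, or how well a
basis fitted in one condition reconstructs data from another.

The reconstruction criterion follows the perturbation-synergy literature:
per-muscle VAF_i = 1 - SS_residual / SS_total with an *uncentered* total
sum of squares, and a basis "generalizes" when VAF > 0.8 in every muscle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DimensionError

__all__ = [
    "PcaBasis",
    "VafReport",
    "pca_fit",
    "n_components_for_vaf",
    "reconstruct_vaf",
    "n_components_for_generalization",
]

#: Generalization criterion: every muscle must be reconstructed with
#: VAF strictly above this fraction.
VAF_GENERALIZATION_THRESHOLD = 0.8


@dataclass
class PcaBasis:
    """An ordered orthonormal basis for a muscle-space point cloud.

    ``components`` is (n_components, n_muscles), rows orthonormal and sorted
    by decreasing explained variance; ``mean`` is the per-muscle mean that
    was removed before fitting (zeros for an uncentered fit).
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratios: np.ndarray
    centered: bool = True

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.explained_variance_ratios = np.atleast_1d(
            np.asarray(self.explained_variance_ratios, dtype=float)
        )
        if self.components.shape[1] != self.mean.shape[0]:
            raise DimensionError("components and mean disagree on the number of muscles")
        if len(self.explained_variance_ratios) != self.components.shape[0]:
            raise DimensionError("one explained-variance ratio per component is required")

    @property
    def n_muscles(self) -> int:
        return self.components.shape[1]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratios)


@dataclass
class VafReport:
    """Variance accounted for by a truncated-basis reconstruction."""

    per_muscle_vaf: np.ndarray
    global_vaf: float
    n_components: int
    generalizes: bool
    threshold: float = VAF_GENERALIZATION_THRESHOLD
    muscle_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_muscle_vaf = np.atleast_1d(np.asarray(self.per_muscle_vaf, dtype=float))


def _as_matrix(data) -> np.ndarray:
    """Accept an EmgMatrix-like object (``.values``) or a bare array,
    muscles x conditions."""
    values = getattr(data, "values", data)
    X = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.all(np.isfinite(X)):
        raise DimensionError("data must be finite")
    return X


def pca_fit(data, centered: bool = True) -> PcaBasis:
    """Fit principal components to a muscles-x-conditions data matrix.

    Components are the eigenvectors of the (centered or uncentered) second
    moment matrix across conditions, ordered by decreasing eigenvalue.  The
    sign of each component is fixed so its largest-magnitude coordinate is
    positive, making the fit deterministic.
    """
    X = _as_matrix(data)
    n_muscles, n_conditions = X.shape
    if n_conditions < 2:
        raise DimensionError("PCA needs at least 2 conditions")
    mean = X.mean(axis=1) if centered else np.zeros(n_muscles)
    Xc = X - mean[:, None]
    total = float(np.sum(Xc**2))
    if total <= 0.0:
        warnings.warn(
            "all conditions identical; returning a zero-variance basis", stacklevel=2
        )
        comps = np.eye(n_muscles)
        return PcaBasis(mean, comps, np.zeros(n_muscles), centered=centered)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    comps = U.T  # rows are components in muscle space
    # deterministic sign: largest-magnitude coordinate positive
    for r in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[r])))
        if comps[r, i] < 0:
            comps[r] = -comps[r]
    ratios = S**2 / np.sum(S**2)
    return PcaBasis(mean, comps, ratios, centered=centered)


def n_components_for_vaf(data, threshold: float, centered: bool = True) -> int:
    """Smallest number of components whose cumulative explained variance
    strictly exceeds ``threshold`` ("more than" the stated fraction).

    ``threshold = 0`` returns 1, the smallest positive count.
    """
    if not 0.0 <= threshold < 1.0:
        raise ConfigError(f"threshold must be in [0, 1), got {threshold}")
    basis = pca_fit(data, centered=centered)
    cum = basis.cumulative_variance()
    above = np.nonzero(cum > threshold)[0]
    if len(above) == 0:  # numerically possible when cum tops out below threshold
        return basis.n_components
    return int(above[0]) + 1


def reconstruct_vaf(
    basis: PcaBasis,
    n_components: int,
    data,
    threshold: float = VAF_GENERALIZATION_THRESHOLD,
    muscle_names: list[str] | None = None,
) -> VafReport:
    """Reconstruct data with the first ``n_components`` of a basis and report
    per-muscle and global VAF.

    The basis mean is subtracted before projection and re-added after, so a
    basis fitted on one posture reconstructs another posture's data around
    the *reference* mean.  VAF uses the uncentered total sum of squares:
    ``VAF_i = 1 - sum_c (x_ic - xhat_ic)^2 / sum_c x_ic^2``.  A muscle that
    is never active (zero denominator) scores 1 if its residual is also
    zero, else 0.
    """
    X = _as_matrix(data)
    if X.shape[0] != basis.n_muscles:
        raise DimensionError(
            f"data has {X.shape[0]} muscles but the basis was fitted on {basis.n_muscles}"
        )
    if not 1 <= n_components <= basis.n_components:
        raise ConfigError(
            f"n_components must be in [1, {basis.n_components}], got {n_components}"
        )
    P = basis.components[:n_components]  # (k, n_muscles)
    Xc = X - basis.mean[:, None]
    Xhat = basis.mean[:, None] + P.T @ (P @ Xc)
    resid = np.sum((X - Xhat) ** 2, axis=1)
    total = np.sum(X**2, axis=1)
    vaf = np.empty(basis.n_muscles)
    zero = total <= 0.0
    if np.any(zero):
        warnings.warn(
            "muscle(s) with zero total activation; VAF set to 1 where the residual "
            "is also zero, else 0",
            stacklevel=2,
        )
        vaf[zero] = np.where(resid[zero] <= 1e-300, 1.0, 0.0)
    nz = ~zero
    vaf[nz] = 1.0 - resid[nz] / total[nz]
    grand_total = float(np.sum(total))
    global_vaf = 1.0 - float(np.sum(resid)) / grand_total if grand_total > 0 else 1.0
    return VafReport(
        per_muscle_vaf=vaf,
        global_vaf=global_vaf,
        n_components=n_components,
        generalizes=bool(np.all(vaf > threshold)),
        threshold=threshold,
        muscle_names=muscle_names or [],
    )


def n_components_for_generalization(
    basis: PcaBasis, data, threshold: float = VAF_GENERALIZATION_THRESHOLD
) -> int:
    """Smallest number of components whose self-reconstruction meets the
    per-muscle criterion (VAF > threshold in *every* muscle).

    The global cumulative-variance rule can be satisfied by components that
    leave individual muscles poorly reconstructed; cross-posture
    generalization is judged per muscle, so the reference basis size must be
    chosen by the same per-muscle rule.  With the full basis the
    reconstruction is exact, so a valid count always exists.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, basis.n_components + 1):
            if reconstruct_vaf(basis, k, data, threshold=threshold).generalizes:
                return k
    return basis.n_components
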