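"""Serialization: limb-model JSON, CSV exports, H-representation text,
and run configuration.

The limb-model interchange format is JSON with keys ``muscle_names``,
``joint_names``, ``moment_arms`` (nested lists, row-major, meters),
``jacobian``, ``max_forces`` (newtons), ``posture`` (radians) and the
optional keys ``wrench_labels``, ``moment_arm_coeffs``, ``link_lengths``,
``condition_bound``.  Matrices also export to CSV with header rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .limb import LimbModel
from .polytope import ActivationPolytope

__all__ = [
    "model_to_dict",
    "model_to_json",
    "model_from_dict",
    "validate_model",
    "matrix_to_csv",
    "movements_to_csv",
    "emg_to_csv",
    "polytope_to_hrep",
    "hrep_to_polytope",
    "RunConfig",
]

_REQUIRED_KEYS = ("muscle_names", "joint_names", "moment_arms", "jacobian", "max_forces", "posture")


def model_to_dict(model: LimbModel) -> dict:
    d = {
        "muscle_names": list(model.muscle_names),
        "joint_names": list(model.joint_names),
        "moment_arms": model.moment_arms.tolist(),
        "jacobian": model.jacobian.tolist(),
        "max_forces": model.max_forces.tolist(),
        "posture": model.posture.tolist(),
        "wrench_labels": list(model.wrench_labels),
        "condition_bound": model.condition_bound,
    }
    if model.moment_arm_coeffs is not None:
        d["moment_arm_coeffs"] = model.moment_arm_coeffs.tolist()
    if model.link_lengths is not None:
        d["link_lengths"] = model.link_lengths.tolist()
    return d


def model_to_json(model: LimbModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def model_from_dict(data: dict) -> LimbModel:
    violations = [f"missing required key {k!r}" for k in _REQUIRED_KEYS if k not in data]
    if violations:
        raise SchemaError("invalid limb model", violations)
    try:
        return LimbModel(
            muscle_names=list(data["muscle_names"]),
            joint_names=list(data["joint_names"]),
            moment_arms=np.asarray(data["moment_arms"], dtype=float),
            jacobian=np.asarray(data["jacobian"], dtype=float),
            max_forces=np.asarray(data["max_forces"], dtype=float),
            posture=np.asarray(data["posture"], dtype=float),
            wrench_labels=list(data.get("wrench_labels") or []),
            moment_arm_coeffs=(
                np.asarray(data["moment_arm_coeffs"], dtype=float)
                if data.get("moment_arm_coeffs") is not None
                else None
            ),
            link_lengths=(
                np.asarray(data["link_lengths"], dtype=float)
                if data.get("link_lengths") is not None
                else None
            ),
            condition_bound=float(data.get("condition_bound", 1e8)),
        )
    except Exception as exc:  # invariant violations, bad shapes, bad dtypes
        raise SchemaError("invalid limb model", [str(exc)]) from exc


def validate_model(path: str | Path) -> LimbModel:
    """Parse and invariant-check a limb-model JSON file.

    Raises :class:`SchemaError` carrying a structured list of violations
    (malformed JSON, missing keys, dimension mismatches, nonpositive maximum
    forces, ...), each named.
    """
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"model file not found: {p}", [f"no such file: {p}"])
    try:
        data = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(
            f"malformed JSON in {p}", [f"line {exc.lineno}, column {exc.colno}: {exc.msg}"]
        ) from exc
    if not isinstance(data, dict):
        raise SchemaError(f"model file {p} must contain a JSON object", ["top level is not an object"])
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------

def matrix_to_csv(matrix: np.ndarray, path: str | Path, row_labels=None, col_labels=None) -> None:
    M = np.atleast_2d(np.asarray(matrix))
    df = pd.DataFrame(M, index=row_labels, columns=col_labels)
    df.to_csv(path, index=row_labels is not None)


def movements_to_csv(movements, path: str | Path) -> None:
    X = movements.displacements
    cols = [f"d{i}" for i in range(X.shape[1])]
    if X.shape[1] >= 2:
        cols[0], cols[1] = "dx_m", "dy_m"
    if X.shape[1] == 3:
        cols[2] = "dphi_rad"
    pd.DataFrame(X, columns=cols).to_csv(path, index=False)


def emg_to_csv(emg, path: str | Path) -> None:
    pd.DataFrame(emg.values, index=emg.muscle_names, columns=emg.condition_labels).to_csv(path)


# ---------------------------------------------------------------------------
# H-representation text format
# ---------------------------------------------------------------------------

def polytope_to_hrep(poly: ActivationPolytope, path: str | Path) -> None:
    """Write a polytope as whitespace-separated rows ``type c1 ... cn rhs``.

    ``eq`` rows encode ``c . a = rhs``; ``lb``/``ub`` rows encode the box
    bounds ``a_i >= rhs`` / ``a_i <= rhs`` with a unit coefficient vector.
    """
    n = poly.n_muscles
    lines = [f"# activation polytope, n_muscles={n}"]
    for row, rhs in zip(poly.a_eq, poly.b_eq):
        lines.append("eq " + " ".join(repr(float(v)) for v in row) + f" {float(rhs)!r}")
    for i in range(n):
        e = ["0.0"] * n
        e[i] = "1.0"
        lines.append("lb " + " ".join(e) + " 0.0")
        lines.append("ub " + " ".join(e) + " 1.0")
    Path(path).write_text("\n".join(lines) + "\n")


def hrep_to_polytope(path: str | Path) -> ActivationPolytope:
    rows, rhs = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind, coeffs, b = parts[0], [float(x) for x in parts[1:-1]], float(parts[-1])
        if kind == "eq":
            rows.append(coeffs)
            rhs.append(b)
        elif kind not in ("lb", "ub"):
            raise SchemaError(f"unknown H-rep row type {kind!r}", [line])
    if not rows:
        raise SchemaError("H-rep file contains no equality rows", [])
    return ActivationPolytope(np.array(rows), np.array(rhs))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

BUILTIN_MODELS = ("schematic", "finger", "finger-flexed", "leg")


@dataclass
class RunConfig:
    """Fully serializable configuration of an analysis run.

    ``model`` is a builtin name (schematic, finger, finger-flexed, leg) or a
    path to a limb-model JSON file.  A run's config plus the package version
    reproduce its outputs bit for bit.
    """

    model: str = "finger"
    analysis: str = "both"
    k_directions: int = 16
    magnitude_m: float = 0.10
    increment_N: float = 1.0
    threshold: float = 0.8
    transform: str = "rectified_linear"
    gain: float = 1.0
    zero_components: tuple[str, ...] = ("tz",)
    seed: int = 0
    outdir: str = "synergy_out"
    generalization_grid: int = 5
    generalization_extent: float = 0.15

    def __post_init__(self) -> None:
        self.zero_components = tuple(self.zero_components)
        self.validate()

    def validate(self) -> None:
        if self.analysis not in ("feedback", "feedforward", "both"):
            raise ConfigError(f"unknown analysis {self.analysis!r}")
        if self.k_directions < 2:
            raise ConfigError("k_directions must be >= 2")
        if self.magnitude_m <= 0:
            raise ConfigError("magnitude_m must be positive")
        if self.increment_N <= 0:
            raise ConfigError("increment_N must be positive")
        if not 0.0 <= self.threshold < 1.0:
            raise ConfigError("threshold must be in [0, 1)")
        if self.gain < 0:
            raise ConfigError("gain must be nonnegative")
        if self.seed < 0:
            raise ConfigError("seed must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zero_components"] = list(self.zero_components)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {p} must contain a mapping")
        return cls.from_dict(data)
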