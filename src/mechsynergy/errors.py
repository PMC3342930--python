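"""Exception hierarchy for mechsynergy."""


class MechSynergyError(Exception):
    """Base class for all package errors."""


class DimensionError(MechSynergyError):
    """Shapes of arrays passed to an operation are inconsistent."""


class SingularityError(MechSynergyError):
    """A Jacobian (or other kinetostatic map) is singular or ill-conditioned."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class RankError(MechSynergyError):
    """A regression design or constraint matrix is rank deficient."""


class SizeCapError(MechSynergyError):
    """A combinatorial operation was refused because the problem is too large."""


class ConfigError(MechSynergyError):
    """An analysis configuration value is invalid or unknown."""


class SchemaError(MechSynergyError):
    """A model or config file does not conform to the expected schema."""

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []
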