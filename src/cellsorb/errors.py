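"""Exception hierarchy shared across the package."""


class CellsorbError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CellsorbError, ValueError):
    """A physical quantity or dataset violates its preconditions."""


class FitError(CellsorbError, RuntimeError):
    """A regression could not be carried out or did not converge."""


class SolverError(CellsorbError, RuntimeError):
    """The forward simulation failed to converge or became unstable."""


class ConfigError(CellsorbError, ValueError):
    """A run configuration file is missing keys or fails validation."""


class SchemaError(CellsorbError, ValueError):
    """A tabular input does not match its expected schema."""
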