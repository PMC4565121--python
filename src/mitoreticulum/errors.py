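"""Exception hierarchy for the model."""


class MitoReticulumError(Exception):
    """Base class for all package errors."""


class ParameterError(MitoReticulumError, ValueError):
    """A parameter is outside its physical or numerical domain."""


class ConfigError(ParameterError):
    """A configuration file or flag set failed validation."""


class OverloadedCytoskeletonError(MitoReticulumError):
    """The requested mitochondrial mass exceeds the carrying capacity
    n_f * (l2 - l1) of the cytoskeleton; no occupancy 0 <= eps <= 1 exists."""


class EvaluationError(MitoReticulumError):
    """A series or quadrature failed to converge within its caps."""


class SolverError(MitoReticulumError):
    """A root finder failed to bracket or converge (should not happen for
    physical inputs; raised with diagnostics if it does)."""
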