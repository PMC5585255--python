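"""Exception hierarchy shared across the package."""


class TrpGateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TrpGateError):
    """A structure file could not be interpreted (e.g. zero atoms)."""


class ConsistencyError(TrpGateError):
    """Models in a trajectory file disagree with the topology."""


class QueryError(TrpGateError):
    """A selection query used an unknown field or malformed value."""


class SelectionError(TrpGateError):
    """A selection resolved to an empty or otherwise unusable atom set."""


class ConfigurationError(TrpGateError):
    """A simulation or analysis configuration is infeasible or invalid."""


class DegenerateGeometryError(TrpGateError):
    """Geometry (collinear/coincident points) does not support the operation."""


class WindowingError(TrpGateError):
    """Time windows are empty, overlapping or out of order."""


class FitError(TrpGateError):
    """Nonlinear fitting failed to converge from every starting point."""


class IdealizationError(TrpGateError):
    """A single-channel recording could not be idealized (no baseline mode)."""
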