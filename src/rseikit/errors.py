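"""Exception hierarchy used across the pipeline."""


class RseikitError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(RseikitError):
    """An operation received an input with no valid cells."""


class AlignmentError(RseikitError):
    """Two grids entering a pairwise operation are not co-registered."""


class DegenerateInputError(RseikitError):
    """Input is constant or rank-deficient where variation is required."""


class ConfigurationError(RseikitError):
    """A configuration value is missing, unknown, or inconsistent."""


class SpecificationError(RseikitError):
    """A synthetic-scene specification is internally infeasible."""


class ContractViolationError(RseikitError):
    """A value violates a documented range contract (e.g. RSEI outside [0,1])."""
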