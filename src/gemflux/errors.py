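"""Exception hierarchy. Exit codes match the CLI contract."""


class GemfluxError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(GemfluxError):
    """Invalid input, configuration, or model structure."""

    exit_code = 2


class SolverError(GemfluxError):
    """The LP backend failed or returned an unexpected status."""

    exit_code = 3


class InfeasibleModelError(GemfluxError):
    """A model (or constrained variant) admits no feasible flux state."""

    exit_code = 4


class NoObjectiveError(ValidationError):
    """No (or more than one) biomass objective could be identified."""


class SBMLParseError(ValidationError):
    """An SBML document could not be parsed into a model."""
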