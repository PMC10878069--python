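"""Exception hierarchy shared across the package."""


class ParafluxError(Exception):
    """Base class for all package-specific errors."""


class ModelStructureError(ParafluxError):
    """A model violates a structural invariant (dangling ids, bad bounds...)."""


class FormatError(ParafluxError):
    """A serialized model or data table cannot be interpreted."""


class SBMLParseError(FormatError):
    """Malformed SBML; carries the libsbml line number when available."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class InfeasibleError(ParafluxError):
    """The constrained LP has no feasible flux distribution."""


class UnboundedError(ParafluxError):
    """The LP objective is unbounded under the given constraints."""


class ConfigurationError(ParafluxError):
    """A protocol could not locate a required model feature (e.g. the
    non-growth ATP hydrolysis reaction)."""


class FittingError(ParafluxError):
    """Regression input is degenerate or yields an undefined parameter."""
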