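"""Exception hierarchy shared across the package."""


class OntoshapeError(Exception):
    """Base class for all ontoshape errors."""


class ArgumentError(OntoshapeError, ValueError):
    """A caller-supplied argument violates a precondition."""


class FormatError(OntoshapeError):
    """An input file does not parse under its declared format."""


class ValidationError(OntoshapeError):
    """An ontology graph (or module) violates a structural invariant."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ConvergenceError(OntoshapeError):
    """Raised by the CLI when convergence was required but not reached."""
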