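"""Exception hierarchy shared across the package."""


class CsbenchError(Exception):
    """Base class for all package errors."""


class ParseError(CsbenchError):
    """A delimited input file could not be parsed into valid objects."""


class ValidationError(CsbenchError):
    """A domain object violates one of its invariants."""


class ConfigurationError(CsbenchError):
    """A run configuration or simulation profile is infeasible."""


class AnalysisError(CsbenchError):
    """An analysis precondition is not met (e.g. no qualifying site)."""
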