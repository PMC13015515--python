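"""Exception hierarchy shared across the package."""


class RTNetsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RTNetsError):
    """Invalid configuration values (bad proportions, ranges, paths)."""


class FormatError(RTNetsError):
    """Unparseable or unrecognizable input file layout."""


class SchemaError(RTNetsError):
    """Structurally valid file whose content violates the expected schema."""


class InsufficientDataError(RTNetsError):
    """Too few usable samples/genes/probes to carry out an operation."""


class EmptyNetworkError(RTNetsError):
    """Edge filtering left no edges to build a network from."""


class NumericalError(RTNetsError):
    """Numerical failure (e.g. singular covariance after regularization)."""


class DegenerateRTWarning(UserWarning):
    """Replication-timing proxy degenerate (zero variance across windows)."""
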