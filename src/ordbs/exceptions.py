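"""Exception hierarchy shared across the package."""


class OrdbsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OrdbsError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateNodeError(OrdbsError, ValueError):
    """A node retains too few non-intervened experiments for estimation."""


class ModelError(OrdbsError, ValueError):
    """A model object is structurally invalid (e.g. a cyclic weight matrix)."""


class NumericalError(OrdbsError, RuntimeError):
    """A linear system stayed singular even after ridge regularization."""


class FormatError(OrdbsError, ValueError):
    """An input file does not conform to the documented format."""


class MetricUndefinedError(OrdbsError, ValueError):
    """A quality metric is undefined for the given inputs (e.g. ROC without positives)."""
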