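"""Exception hierarchy for cmrpump.

Every error raised by the package derives from :class:`CmrPumpError`, so
callers (and the CLI) can distinguish domain failures from programming
errors.
"""


class CmrPumpError(Exception):
    """Base class for all cmrpump errors."""


class ValidationError(CmrPumpError):
    """Input file or table violates the documented schema or an invariant."""


class GeometryError(CmrPumpError):
    """Degenerate or invalid planar geometry (self-intersection, coincident
    points, apex on the AV line, ...)."""


class MissingLandmarkError(CmrPumpError):
    """A labelled AV-plane point required by the requested metric is absent."""


class MissingViewError(CmrPumpError):
    """A long-axis view required by the requested metric is absent."""


class DomainError(CmrPumpError):
    """Arguments outside the mathematical domain of an operation
    (zero stroke volume, non-positive cardiac output, empty sample, ...)."""


class ConvergenceError(CmrPumpError):
    """Iterative fit failed to converge or the data are separated."""
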