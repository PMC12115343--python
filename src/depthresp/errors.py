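"""Exception hierarchy shared across the package.

All errors raised by depthresp derive from :class:`DepthRespError`, so callers
(and the CLI) can catch one base class and translate it into a machine-readable
diagnostic.
"""


class DepthRespError(Exception):
    """Base class for all depthresp errors."""


class ConfigError(DepthRespError):
    """Invalid configuration or parameter value."""


class InvalidDepthError(DepthRespError):
    """A depth value required by an operation is invalid (non-positive)."""


class BoundsError(DepthRespError):
    """A pixel coordinate falls outside the sensor frame."""


class EmptyROIError(DepthRespError):
    """The effective region of interest contains no valid pixel."""


class DetectionFailureError(DepthRespError):
    """Automatic ROI detection found no coherent motion region.

    Callers are expected to fall back to a fixed ROI when one is configured.
    """


class NoCycleError(DepthRespError):
    """No complete respiratory cycle could be identified.

    Parameters
    ----------
    message : str
        Human-readable summary.
    diagnostic : dict, optional
        Structured detail (number of raw peaks/troughs found, signal range,
        ...) carried into reports and CLI error output.
    """

    def __init__(self, message: str, diagnostic: dict | None = None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


class FormatError(DepthRespError):
    """A sequence container or report file failed validation."""


class AlignmentError(DepthRespError):
    """Two series expected to share a time base do not."""
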