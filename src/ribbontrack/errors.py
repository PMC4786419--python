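"""Exception hierarchy for ribbontrack.

Configuration problems, geometry problems and data-loading problems are kept
distinct so the CLI can map them to distinct exit codes.
"""


class RibbontrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RibbontrackError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class GeometryError(RibbontrackError, ValueError):
    """Scene/scan geometry is inconsistent (e.g. scan line misses the membrane)."""


class CalibrationError(RibbontrackError, RuntimeError):
    """PSF calibration failed (no spot above background)."""


class NoSpotError(RibbontrackError, RuntimeError):
    """A fit was requested on data with no detectable emitter."""


class NoEventError(RibbontrackError, RuntimeError):
    """Decline classification requested on a trace with no decline."""


class LoadError(RibbontrackError, IOError):
    """Imaging data or its metadata sidecar could not be loaded."""


class PropagationError(RibbontrackError, RuntimeError):
    """An unconverged fit was used where a converged one is required."""
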