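"""Exception hierarchy.

Errors that stem from user-supplied inputs (files, configuration) derive
from :class:`InputError` so the command line can map them to exit code 1;
anything else propagates and maps to exit code 2.
"""


class DidaError(Exception):
    """Base class for all errors raised by this package."""


class InputError(DidaError):
    """A user-supplied file or value is unusable (unreadable, missing, malformed)."""


class FormatError(InputError):
    """An image or array has an unsupported layout (channel count, bit depth)."""


class EmptyRecordingError(InputError):
    """A recording contained zero frames."""


class ConfigurationError(DidaError):
    """Invalid analysis or simulation configuration (ROI, thresholds, geometry)."""


class NoContrastError(DidaError):
    """Tablet recording is indistinguishable from the background recording."""


class OutOfRangeError(DidaError):
    """A requested timepoint lies outside the span of a recording or profile."""


class DegenerateVarianceError(DidaError):
    """Both groups have zero variance but different means; a t-statistic is undefined."""
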