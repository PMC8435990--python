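"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`PitScanError` so callers (and the
CLI) can name the failing stage without string matching.
"""


class PitScanError(Exception):
    """Base class for all pitscan errors."""


class InputError(PitScanError):
    """Invalid user-supplied value or argument."""


class FormatError(PitScanError):
    """Malformed image stack or data file."""


class DetectionError(PitScanError):
    """A slice could not be contoured (e.g. empty cross-section)."""


class DegenerateSliceError(PitScanError):
    """A slice is too degraded for the radius fit to converge."""


class FitError(PitScanError):
    """A regression fit is degenerate or failed to converge."""
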