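"""Exception hierarchy for posturekit.

All toolkit errors derive from :class:`PosturekitError` so callers (and the
CLI) can distinguish usage/file problems from computational degeneracies.
"""


class PosturekitError(Exception):
    """Base class for all posturekit errors."""


class FormatError(PosturekitError):
    """A file does not follow the expected tabular dialect (e.g. missing column)."""


class DataError(PosturekitError):
    """File parsed but the data violate an invariant (e.g. non-increasing time)."""


class ConfigError(PosturekitError):
    """Run configuration violates an invariant (e.g. negative rate)."""


class ParameterError(PosturekitError):
    """An operation was called with invalid parameters (e.g. cutoff >= Nyquist)."""


class CalibrationError(PosturekitError):
    """Calibration recordings are unusable (e.g. loaded mean <= zero mean)."""


class AlignmentError(PosturekitError):
    """Dual-device alignment failed (zero variance, excessive lag, no overlap)."""


class SegmentError(PosturekitError):
    """Requested analysis segment does not fit in the available recording."""


class UnloadedPlateError(PosturekitError):
    """Total vertical force fell below the loaded-plate floor."""


class DegenerateDataError(PosturekitError):
    """A statistic is undefined on the given data (e.g. zero total variance)."""
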