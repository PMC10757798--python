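"""Exception hierarchy for dualica.

All library errors derive from :class:`DualICAError` so callers can catch
one base class at pipeline boundaries.
"""


class DualICAError(Exception):
    """Base class for all dualica errors."""


class DuplicateLabelError(DualICAError):
    """A gene or condition label occurs more than once."""


class MissingValueError(DualICAError):
    """The input matrix contains a missing (NA/empty) cell."""


class MatrixParseError(DualICAError):
    """A cell of the input matrix could not be parsed as a number."""


class DegenerateColumnError(DualICAError):
    """A column has zero variance and cannot be standardized."""


class SampleTooSmallError(DualICAError):
    """A sample is too short for the D'Agostino omnibus test (< 8)."""


class DegenerateSampleError(DualICAError):
    """A sample has zero variance; normality is undefined."""


class TooFewPointsError(DualICAError):
    """Knee detection needs at least 3 points."""


class CollinearityError(DualICAError):
    """The regression design matrix is rank deficient."""


class GMTParseError(DualICAError):
    """A GMT gene-set file line is malformed."""


class ConfigError(DualICAError):
    """A pipeline configuration value is out of range or inconsistent."""
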