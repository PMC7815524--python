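"""Exception hierarchy with CLI exit codes.

Exit-code contract: 0 success, 2 validation error, 3 data/format error,
4 degenerate-statistics error.
"""


class FieldLabError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FieldLabError):
    """Invalid parameter, configuration value, or precondition violation."""

    exit_code = 2


class FormatError(FieldLabError):
    """Malformed input file (names the offending line where possible)."""

    exit_code = 3


class DataError(FieldLabError):
    """Structurally valid file with physically inconsistent contents."""

    exit_code = 3


class DetectionError(DataError):
    """No stimulus artifact found and no annotation available."""


class AnalysisError(FieldLabError):
    """A protocol-level analysis could not be completed on this recording."""

    exit_code = 3


class DegenerateStatisticsError(FieldLabError):
    """Sample too small or too degenerate for the requested statistic."""

    exit_code = 4
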