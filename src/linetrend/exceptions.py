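"""Error taxonomy shared by all analysis modules.

Each class maps to a distinct CLI exit code (see :mod:`linetrend.cli_report`).
"""


class LinetrendError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LinetrendError):
    """Invalid user configuration: bad column map, k=1 group test, reps=0 ..."""

    exit_code = 2


class DataError(LinetrendError):
    """The input data violate a dataset invariant (e.g. duplicate subject/time)."""

    exit_code = 3


class FeasibilityError(LinetrendError):
    """A method cannot be applied to these data (unbalanced wide pivot,
    N - k <= m - 1 for MANOVA, UNS parameter count exceeding the data)."""

    exit_code = 4


class DegenerateTestError(LinetrendError):
    """A test statistic is undefined (zero variance of the summaries)."""

    exit_code = 5


class UndefinedSummaryError(LinetrendError):
    """A per-subject summary is undefined (slope with < 2 distinct times)."""

    exit_code = 5


class NumericalError(LinetrendError):
    """Singular covariance or other numerical failure during evaluation."""

    exit_code = 6
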