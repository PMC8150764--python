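"""Exception hierarchy for wristpa."""


class WristPAError(Exception):
    """Base class for all wristpa errors."""


class InputError(WristPAError, ValueError):
    """Invalid argument or precondition violation."""


class FormatError(InputError):
    """Malformed input file (missing columns, non-monotonic timestamps, ...)."""


class RateError(InputError):
    """Declared sampling rate inconsistent with observed sample spacing."""


class DegenerateLabelsError(InputError):
    """Label vector with fewer than two distinct classes."""


class EmptyDatasetError(InputError):
    """Task dataset with zero rows after filtering."""


class UndefinedMetricError(WristPAError):
    """A metric is undefined for the given inputs (e.g. a class absent)."""
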