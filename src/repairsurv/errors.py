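"""Exception types shared across the package."""


class RepairSurvError(Exception):
    """Base class for package errors."""


class FormatError(RepairSurvError, ValueError):
    """A flat file does not conform to the expected dialect."""


class DegenerateInputError(RepairSurvError, ValueError):
    """Input is structurally valid but statistically untestable
    (constant vector, empty group, no events, ...)."""


class CollinearityError(RepairSurvError, ValueError):
    """Regression design matrix is rank deficient."""
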