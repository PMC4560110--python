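"""Exception hierarchy for dynconn."""


class DynconnError(Exception):
    """Base class for all dynconn errors."""


class DataValidationError(DynconnError):
    """Raised when input data violate a structural precondition."""


class SingularCovarianceError(DynconnError):
    """Raised when a covariance matrix is singular beyond repair."""
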