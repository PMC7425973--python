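"""Exception types shared across the package."""


class PhasecostError(Exception):
    """Base class for package errors."""


class ConfigError(PhasecostError, ValueError):
    """Invalid configuration; the message names the offending field."""


class DataError(PhasecostError, ValueError):
    """Malformed input data (unsorted months, duplicates, missing fields)."""


class EstimationError(PhasecostError, ValueError):
    """An estimate is undefined for the supplied inputs."""


class SingularDesignError(EstimationError):
    """Design matrix is rank-deficient after the within-transformation."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message
            or "singular design after within-patient demeaning; offending "
            f"columns: {self.columns}"
        )
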