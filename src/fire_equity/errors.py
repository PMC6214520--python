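"""Exception hierarchy shared across the pipeline stages."""


class FireEquityError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(FireEquityError):
    """A configuration value is structurally invalid (bad shape, range, length)."""


class DataError(FireEquityError):
    """Input data violates a contract (out-of-range value, NaN, missing overlap)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class DegenerateDesignError(DataError):
    """A regression design matrix is rank-deficient (e.g. constant predictor)."""


class PipelineError(FireEquityError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
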