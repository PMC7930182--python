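"""Exception types shared across the package."""


class CxscoreError(Exception):
    """Base class for package errors."""


class ValidationError(CxscoreError):
    """Invalid input data or configuration (CLI exit code 2)."""


class SpecError(ValidationError):
    """Invalid simulation specification; message names the offending field."""


class UndefinedScoreError(CxscoreError):
    """Percent change is undefined (zero baseline)."""
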