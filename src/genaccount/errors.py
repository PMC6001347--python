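"""Exception hierarchy for genaccount."""


class GenAccountError(Exception):
    """Base class for all genaccount errors."""


class InvalidInputError(GenAccountError, ValueError):
    """An operation received input violating its preconditions."""


class ProfileParseError(InvalidInputError):
    """A profile CSV file violated the format contract.

    Carries the (1-based, header-inclusive) row number of the first
    offending row when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class CalibrationError(GenAccountError):
    """Profiles cannot be calibrated to the requested targets."""
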