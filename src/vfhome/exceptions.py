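"""Exception hierarchy for the vfhome package."""


class VFHomeError(Exception):
    """Base class for all vfhome errors."""


class FormatError(VFHomeError):
    """A file does not conform to the expected column/format contract."""


class ValidationError(VFHomeError):
    """A field value violates its domain constraints.

    Parameters
    ----------
    message : str
    row : int, optional
        1-based data row number in the source file, when applicable.
    field : str, optional
        Name of the offending field.
    """

    def __init__(self, message, row=None, field=None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class InsufficientDataError(VFHomeError):
    """Too few observations for the requested statistic."""


class DegenerateDesignError(VFHomeError):
    """A regression design matrix is singular (e.g. all times equal)."""


class CalibrationError(VFHomeError):
    """A calibration routine could not meet its targets within tolerance."""
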