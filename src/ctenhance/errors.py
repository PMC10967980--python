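"""Exception types shared across the package."""


class CTEnhanceError(Exception):
    """Base class for package errors."""


class FormatError(CTEnhanceError):
    """A file could not be read in the expected format."""


class SeriesInconsistencyError(FormatError):
    """A DICOM directory mixes slices from more than one series."""


class ValidationError(CTEnhanceError, ValueError):
    """An input value violates a documented contract."""
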