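"""Exception hierarchy shared across the package."""


class FaceBiasError(Exception):
    """Base class for all package-specific errors."""


class PanelFormatError(FaceBiasError):
    """A data file does not match the expected dialect (e.g. missing column)."""


class PanelValidationError(FaceBiasError):
    """Field values violate the data model (e.g. rating out of range)."""


class ConfigurationError(FaceBiasError):
    """An analysis or simulation parameter is outside its allowed set."""


class DegenerateDataError(FaceBiasError):
    """A selection is too small or too uniform for the requested statistic."""


class EmptySelectionError(FaceBiasError):
    """A condition/label/phase selection matched no records."""
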