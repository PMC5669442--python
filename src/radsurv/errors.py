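"""Exception hierarchy for the pipeline."""


class RadsurvError(Exception):
    """Base class for all package errors."""


class FormatError(RadsurvError):
    """A file could not be read in the requested/advertised format."""


class GeometryError(RadsurvError):
    """Volume/mask grids or spacings are inconsistent."""


class ValidationError(RadsurvError):
    """A domain invariant was violated (empty mask, NaN intensities, ...)."""


class SchemaError(RadsurvError):
    """A cohort table is missing required columns or has unparseable values."""


class ConfigError(RadsurvError):
    """An invalid configuration value (nonpositive bin width, bad threshold)."""


class DegenerateInputError(RadsurvError):
    """Input too small or too uniform for the requested statistic."""


class ContractError(RadsurvError):
    """An intermediate object does not satisfy its documented contract."""
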