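"""Exception hierarchy shared across nodulekit modules."""


class NodulekitError(Exception):
    """Base class for all nodulekit errors."""


class PackingError(NodulekitError):
    """Requested nodule field cannot be packed without overlaps."""


class UnthresholdableError(NodulekitError):
    """Input has no intensity contrast to threshold."""


class EmptyWellError(NodulekitError):
    """Both channels are empty after background subtraction."""


class MissingControlError(NodulekitError):
    """No NT control wells available for normalization."""


class DegenerateInputError(NodulekitError):
    """Statistical test input has zero variance or too few values."""


class OutOfRangeError(NodulekitError):
    """A crossing or interpolation target lies outside the data range."""


class BandMismatchError(NodulekitError):
    """Requested wavelength is not on the cube's band axis."""


class CalibrationError(NodulekitError):
    """Calibration curve is invalid (non-monotone or ill-posed)."""


class SeriesTruncationError(NodulekitError):
    """Analytic series did not converge within the term budget."""


class ConfigError(NodulekitError):
    """Run configuration failed schema validation."""


class MissingInputError(NodulekitError):
    """A pipeline stage is missing a required input file."""
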