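"""Exception hierarchy shared across the package."""


class NeuroRamanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NeuroRamanError, ValueError):
    """A parameter violates its documented domain."""


class SpectrumFormatError(NeuroRamanError, ValueError):
    """A spectrum file could not be parsed; message names the offending line."""


class CalibrationError(NeuroRamanError, ValueError):
    """Wavenumber calibration failed (too few anchors or non-monotone map)."""


class RangeError(NeuroRamanError, ValueError):
    """A requested grid or window lies outside the available data range."""


class DataQualityError(NeuroRamanError, ValueError):
    """The data look broken (e.g. too many points flagged as spikes)."""


class NormalizationError(NeuroRamanError, ValueError):
    """Vector normalization is undefined (zero vector on the norm range)."""


class StratificationError(NeuroRamanError, ValueError):
    """A cross-validation fold lost one of the classes."""


class UndefinedMetricError(NeuroRamanError, ValueError):
    """A confusion metric has a zero denominator."""
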