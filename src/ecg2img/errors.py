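"""Exception hierarchy shared across the toolkit.

Every failure mode named in a module contract maps to one subclass of
:class:`ECGToolkitError`, so callers can catch either the precise condition
or anything raised by the package.
"""


class ECGToolkitError(Exception):
    """Base class for all errors raised by ecg2img."""


class ParseError(ECGToolkitError):
    """Malformed text input (ragged row, non-numeric cell, ...)."""


class EmptyInputError(ECGToolkitError):
    """An input that must be non-empty is empty."""


class UnsupportedFormatError(ECGToolkitError):
    """Binary input is not the documented MFER subset."""


class TruncationError(ECGToolkitError):
    """Binary input ends before a declared value or block is complete."""


class CapacityError(ECGToolkitError):
    """A record cannot be represented within the format's field limits."""


class ShapeError(ECGToolkitError):
    """Array dimensions do not match the operation's contract."""


class MissingLeadError(ECGToolkitError):
    """A required ECG lead is absent and cannot be derived."""


class PartitionError(ECGToolkitError):
    """A sequence cannot be split into the requested number of segments."""


class DimensionError(ECGToolkitError):
    """Non-positive or otherwise invalid output dimensions."""


class ConfigurationError(ECGToolkitError):
    """Invalid model or run configuration (unknown backbone id, ...)."""


class LeakageError(ECGToolkitError):
    """A patient's images appear in more than one of train/val/test."""


class SamplingError(ECGToolkitError):
    """An undersampling request exceeds the available population."""


class ProtocolError(ECGToolkitError):
    """Cross-validation protocol cannot be satisfied (k too small, ...)."""


class UndefinedMetricError(ECGToolkitError):
    """A metric's denominator is zero or a class is absent."""


class UnsupportedModelError(ECGToolkitError):
    """The model does not expose what an explanation method needs."""


class LayoutError(ECGToolkitError):
    """Attribution was asked for a panel layout it does not know."""


class ParameterError(ECGToolkitError):
    """Synthetic-generator parameters are out of their valid range."""
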