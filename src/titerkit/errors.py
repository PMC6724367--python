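"""Exception types shared across the toolkit."""


class TiterkitError(Exception):
    """Base class for all titerkit errors."""


class CapacityError(TiterkitError):
    """Requested objects cannot be placed at the requested separation."""


class NoSampleError(TiterkitError):
    """An operation requiring foreground signal was given an empty stack."""


class ShallowStackError(TiterkitError):
    """Stack does not span enough focal planes for half-depth counting."""


class UndefinedRedundancyError(TiterkitError):
    """No components were examined, so a redundancy fraction is undefined."""


class InvalidCurveError(TiterkitError):
    """A standard curve is unusable (e.g. non-negative slope)."""


class InsufficientDataError(TiterkitError):
    """Too few observations for the requested procedure."""


class DegenerateDataError(TiterkitError):
    """Data carry no variation where the procedure requires some."""


class UndefinedRatioError(TiterkitError):
    """Relative titer ratio with a zero-copy denominator."""


class SchemaError(TiterkitError):
    """Input table does not match the expected schema."""
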