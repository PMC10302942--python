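"""Exception hierarchy for the toolkit.

Everything raised on bad user input derives from :class:`InputError`; scenario
parameterization problems raise :class:`ConfigurationError`. Numerically
*undefined* results (zero-variance images, featureless templates) get their own
types so callers can distinguish "instrument fault" from "bad call".
"""


class BiofoulmonError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(BiofoulmonError, ValueError):
    """Invalid scenario or operation parameterization."""


class InputError(BiofoulmonError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class FormatError(InputError):
    """A file does not match the expected on-disk layout."""


class DimensionError(InputError):
    """Array shapes incompatible with the requested operation."""


class FeaturelessTemplateError(BiofoulmonError, ValueError):
    """Template has zero variance; normalized cross-correlation is undefined."""


class UndefinedPeakError(BiofoulmonError, ValueError):
    """Every placement in an NCC map is undefined."""


class ExcessiveMotionError(BiofoulmonError, ValueError):
    """Estimated translation exceeds the movement room left by the crop margins."""


class UndefinedSimilarityError(BiofoulmonError, ArithmeticError):
    """Pearson r undefined because one image has zero variance.

    Deliberately not a numeric sentinel: a constant frame is an instrument
    fault, not similarity evidence.
    """
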