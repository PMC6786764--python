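"""Exception types shared across the package."""


class SpecmammoError(Exception):
    """Base class for package errors."""


class RangeError(SpecmammoError, ValueError):
    """A query fell outside a table's tabulated span."""


class PlacementError(SpecmammoError, ValueError):
    """A phantom feature does not fit inside the configured extent."""


class ConfigurationError(SpecmammoError, ValueError):
    """An invalid or incomplete configuration (missing table, singular basis...)."""


class CorrectionError(SpecmammoError, ValueError):
    """Flat/dark correction cannot be applied (non-positive flat-dark pixels)."""


class UndefinedCnrError(SpecmammoError, ValueError):
    """CNR is undefined because the noise ROI has zero variance."""


class NoSignalError(SpecmammoError, ValueError):
    """The resolution estimator received an image without usable signal."""


class NoSignalWarning(UserWarning):
    """No frequency band rises above the noise baseline."""
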