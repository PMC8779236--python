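"""Exception hierarchy for titinafm."""


class TitinAFMError(Exception):
    """Base class for all package errors."""


class LayoutError(TitinAFMError):
    """Infeasible or invalid molecule layout geometry."""


class FormatError(TitinAFMError):
    """Malformed height-map, mask, or trace file."""


class FlattenError(TitinAFMError):
    """A scan line has too few background pixels to fit the requested order."""


class DomainError(TitinAFMError):
    """Model evaluated outside its mathematical domain."""


class FitConvergenceError(TitinAFMError):
    """Nonlinear fit failed to converge after the documented restarts."""


class MaskError(TitinAFMError):
    """Mask/height-map shape mismatch or empty mask where one is required."""
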