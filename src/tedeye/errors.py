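"""Structured errors raised by the diagnostic pipeline.

Every error names the stage and the offending input so that a failed run on a
clinical image can be traced to a concrete cause (an empty structure class, an
unreadable scale bar, ...) rather than a bare exception.
"""


class TedEyeError(Exception):
    """Base class for all package errors."""


class DegenerateApertureError(TedEyeError):
    """The eyelid parameters close or invert the palpebral aperture."""

    def __init__(self, upper_apex_px: float, lower_apex_px: float):
        self.upper_apex_px = upper_apex_px
        self.lower_apex_px = lower_apex_px
        super().__init__(
            f"degenerate palpebral aperture: upper apex {upper_apex_px:.1f} px, "
            f"lower apex {lower_apex_px:.1f} px (lids crossed or closed)"
        )


class MissingStructureError(TedEyeError):
    """A required structure class has no pixels in the label mask."""

    def __init__(self, structure: str):
        self.structure = structure
        super().__init__(f"required structure {structure!r} has no pixels in the mask")


class CalibrationError(TedEyeError):
    """The scale-bar strip cannot be converted to a mm-per-pixel factor."""


class LocalizationError(TedEyeError):
    """An eye region is missing from the face localization mask."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"no {side!r} eye region found in the localization mask")


class ConfigurationError(TedEyeError):
    """A network or run configuration violates its invariants."""
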