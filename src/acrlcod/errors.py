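"""Exception types raised by the LCOD pipeline."""


class AcrLcodError(Exception):
    """Base class for package errors."""


class DegenerateInputError(AcrLcodError, ValueError):
    """An input image or profile is degenerate (e.g. constant intensity)."""


class GeometryError(AcrLcodError, ValueError):
    """A geometric precondition is violated (profile too short, bad layout)."""


class SegmentationError(AcrLcodError):
    """The inner contrast disk could not be isolated.

    Carries a per-component diagnostic table (``components``, a pandas
    DataFrame with label, area, equivalent radius and distance to the image
    center) so a failed slice can be inspected.
    """

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components


class RayTooShortError(AcrLcodError):
    """A radial profile was truncated before the outermost hole position."""


class SnrError(AcrLcodError):
    """SNR measurement failed (e.g. no phantom-free corner region)."""
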