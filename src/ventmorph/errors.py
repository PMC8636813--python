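"""Exception types shared across the package."""


class VentmorphError(ValueError):
    """Base class for all package-specific errors."""


class PhantomSpecError(VentmorphError):
    """A phantom specification violates a geometric invariant."""


class DegenerateLandmarksError(VentmorphError):
    """AC/PC/midsagittal landmarks do not define a frame (coincident or collinear)."""


class MissingLabelError(VentmorphError):
    """A required label class is absent from the volume or slice."""


class DegenerateRoofError(VentmorphError):
    """Both ventricular roofs are flat; the callosal angle is undefined."""


class MorphometryError(VentmorphError):
    """An index measurement failed; the message names the failing index."""


class InvalidGeometryError(VentmorphError):
    """A measured quantity violates its anatomical invariant (e.g. ratio >= 1)."""


class ParameterInconsistencyError(VentmorphError):
    """Cohort parameters are inconsistent with their truncation bounds."""


class StatisticsError(VentmorphError):
    """A statistical test is undefined for the given input."""
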