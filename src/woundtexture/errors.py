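"""Exception hierarchy for woundtexture."""


class WoundTextureError(Exception):
    """Base class for all package-specific errors."""


class FrameValidationError(WoundTextureError):
    """A thermal frame violates its invariants (size, finiteness, camera range)."""


class TraceValidationError(WoundTextureError):
    """A planimetry trace is not a simple closed polygon with >= 3 vertices."""


class ThermalIOError(WoundTextureError):
    """A file could not be read or written in the requested dialect."""


class CohortError(WoundTextureError):
    """A cohort table is internally inconsistent (duplicates, label conflicts)."""


class NoWoundFoundError(WoundTextureError):
    """Contour detection could not locate a coherent wound region."""


class DegenerateMaskError(WoundTextureError):
    """Mask refinement emptied the mask, or a mask is unusable for analysis."""


class DegenerateInputError(WoundTextureError):
    """An input is too degenerate for the requested computation."""
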