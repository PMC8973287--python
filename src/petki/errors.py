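"""Exception hierarchy for petki.

Every validation failure raises a subclass of :class:`PetkiError` so callers
(and the CLI) can distinguish user/configuration errors from genuine bugs.
"""


class PetkiError(Exception):
    """Base class for all petki errors."""


class ProtocolError(PetkiError, ValueError):
    """Unknown protocol identifier or malformed frame schedule."""


class ScheduleMismatchError(PetkiError, ValueError):
    """An image carries a schedule incompatible with the requested operation."""


class FramingIncompatibilityError(PetkiError, ValueError):
    """Frame grids cannot be tiled/re-binned exactly as required."""


class CurveError(PetkiError, ValueError):
    """Invalid sampled curve (non-uniform grid, non-finite values, ...)."""


class MaskError(PetkiError, ValueError):
    """Empty mask or mask/image shape mismatch."""


class JunctionError(PetkiError, ValueError):
    """Non-positive or misordered junction values in the hybrid input function."""


class DecompositionError(PetkiError, ValueError):
    """Dual-injection tail fit failed or produced an unphysical decay rate."""


class SupportError(PetkiError, ValueError):
    """A frame schedule falls outside the support of the input-function grid."""


class DegenerateBasisError(PetkiError, ValueError):
    """A basis column is identically zero; the update is undefined."""


class InsufficientDataError(PetkiError, ValueError):
    """Too few frames for the requested fit (e.g. Patlak after t*)."""


class ConfigError(PetkiError, ValueError):
    """Invalid phantom/fit configuration."""
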