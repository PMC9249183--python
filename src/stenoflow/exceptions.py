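"""Exception hierarchy.

Everything raised by stenoflow derives from :class:`StenoflowError`, so
callers can catch one base class.  Most errors are also ``ValueError``
subclasses because they signal invalid numeric input.
"""


class StenoflowError(Exception):
    """Base class for all stenoflow errors."""


class ValidationError(StenoflowError, ValueError):
    """Invalid model definition (segment extents, grids, config keys)."""


class DomainError(StenoflowError, ValueError):
    """A coordinate (axial z or radial r) lies outside its admissible range."""


class GeometryError(StenoflowError, ValueError):
    """Wall geometry is unusable (non-positive radius, missing segment)."""


class PlugOverflowError(StenoflowError, ValueError):
    """Plug-core radius exceeds the local lumen radius."""


class DegenerateStationError(StenoflowError, ValueError):
    """Conductance vanished; the pressure-gradient inversion is undefined."""


class NoFlowError(StenoflowError, ValueError):
    """Yield stress with zero pressure gradient: the fluid cannot move."""


class UndefinedImpedanceError(StenoflowError, ValueError):
    """Impedance requested at zero flux."""


class NormalizationError(StenoflowError, ValueError):
    """A reference (uniform-tube) quantity is zero; the ratio is undefined."""


class InvalidStepError(StenoflowError, ValueError):
    """Finite-difference step too large for the available yielded annulus."""
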