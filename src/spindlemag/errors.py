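"""Exception hierarchy for spindlemag.

Every error raised by the package derives from :class:`SpindleMagError`
so callers can catch the whole family with one clause.
"""


class SpindleMagError(Exception):
    """Base class for all spindlemag errors."""


class InvalidFieldError(SpindleMagError, ValueError):
    """Magnetic field specification is unphysical (e.g. negative B)."""


class InvalidGeometryError(SpindleMagError, ValueError):
    """Microtubule or cell geometry is unphysical (e.g. L <= 0, a < b)."""


class DomainError(SpindleMagError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateBendingError(SpindleMagError, ValueError):
    """Deflection is as large as the filament itself; the chord-projection
    force formula is no longer real-valued."""


class TimestepError(SpindleMagError, ValueError):
    """Simulation timestep is too large for the given event rates."""


class InstabilityError(SpindleMagError, RuntimeError):
    """Simulation state blew up; reduce the timestep."""

    def __init__(self, dt: float, message: str = ""):
        self.dt = dt
        super().__init__(message or f"simulation unstable at dt={dt} s; reduce dt")


class NoRelaxationError(SpindleMagError, ValueError):
    """Time series does not decay; no relaxation time can be extracted."""


class ConfigError(SpindleMagError, ValueError):
    """Configuration file or override is malformed."""


class TrajectoryParseError(SpindleMagError, ValueError):
    """Trajectory CSV could not be parsed."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")
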