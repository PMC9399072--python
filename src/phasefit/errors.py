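"""Exception hierarchy shared across the package."""


class PhasefitError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(PhasefitError):
    """A torsion or angle is undefined because three atoms are collinear."""


class UnparametrisedInstanceError(PhasefitError):
    """A bonded instance in the molecule has no matching parameter."""


class UnderdeterminedSuperpositionError(PhasefitError):
    """Fewer than three atoms selected for a rigid superposition."""


class StreamParseError(PhasefitError):
    """Malformed stream-file content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class DuplicateTermError(StreamParseError):
    """Two dihedral lines with the same type key and multiplicity."""


class IncompleteGridError(PhasefitError):
    """A 2D torsion scan is missing grid cells."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ScanInconsistencyError(PhasefitError):
    """Declared scan angle disagrees with the stored geometry."""


class RingTorsionError(PhasefitError):
    """A ring-internal torsion cannot be driven rigidly."""


class EmptyFitError(PhasefitError):
    """No usable scan rows remain after the energy-cutoff exclusion."""


class UnknownTargetError(PhasefitError):
    """A manual phase override names a (type, n) pair that does not exist."""


class ConfigurationError(PhasefitError):
    """Missing or contradictory configuration (e.g. absent bond orders)."""


class TooSmallGridError(PhasefitError):
    """A profile grid is too small for minimum location."""


class MinimisationError(PhasefitError):
    """Energy minimisation diverged or failed to converge."""
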