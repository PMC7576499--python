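"""Exception hierarchy.

Every error raised by nipflow derives from :class:`NipflowError`, so callers
can catch one base class at pipeline boundaries while tests can assert the
precise failure mode.
"""


class NipflowError(Exception):
    """Base class for all nipflow errors."""


# --- simulation -----------------------------------------------------------


class InvalidParameterError(NipflowError, ValueError):
    """A simulation or estimation parameter violates its invariant."""


class InsufficientDesignError(NipflowError, ValueError):
    """Too few temperatures / points for the requested estimate."""


class InvalidSpecError(NipflowError, ValueError):
    """A synthetic structure or alignment spec is internally inconsistent."""


# --- curve fitting --------------------------------------------------------


class FitDegenerateError(NipflowError):
    """The trace carries no resolvable decay (amplitude below noise floor)."""


class FitFailureError(NipflowError):
    """Nonlinear least squares failed to converge; carries residual info."""

    def __init__(self, message: str, residual_rms: float | None = None):
        super().__init__(message)
        self.residual_rms = residual_rms


class NoReswellingError(NipflowError):
    """Glycerol-shock trace has no interior minimum (no re-swelling phase)."""


class WindowError(NipflowError, ValueError):
    """Regression window shorter than the minimum sample count."""


class InvalidConditionsError(NipflowError, ValueError):
    """Shock conditions are unphysical (e.g. non-positive osmolarity)."""


class InvalidComparisonError(NipflowError, ValueError):
    """Estimates of different kinds (Pf vs Pgly) cannot be compared."""


# --- structures -----------------------------------------------------------


class EmptyStructureError(NipflowError):
    """PDB input contains no ATOM/HETATM records."""


class PDBParseError(NipflowError):
    """Malformed PDB record; ``line_number`` locates the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class UnknownElementError(NipflowError, KeyError):
    """Element missing from the van der Waals radius set (strict mode)."""


class BlockedChannelError(NipflowError):
    """Every profiled plane is sterically blocked."""


class NoOverlapError(NipflowError, ValueError):
    """Two pore profiles share no z range."""


class InvalidBoundaryError(NipflowError, ValueError):
    """Region boundary lies outside the profiled z range."""


# --- alignments -----------------------------------------------------------


class UndefinedIdentityError(NipflowError):
    """No column where both sequences are ungapped."""


class WildTypeMismatchError(NipflowError, ValueError):
    """Mutation spec wild-type does not match the sequence."""

    def __init__(self, position: int, expected: str, found: str):
        super().__init__(
            f"position {position}: expected wild-type {expected!r}, found {found!r}"
        )
        self.position = position
        self.expected = expected
        self.found = found


class NoAnchorError(NipflowError):
    """Alignment column precedes every reference residue."""


# --- configuration / pipeline --------------------------------------------


class ConfigError(NipflowError, ValueError):
    """Run configuration failed validation."""


class StageError(NipflowError):
    """A pipeline stage failed; recorded in the run manifest."""
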