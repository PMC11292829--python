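"""Exception and warning types shared across the package."""


class BilayerError(Exception):
    """Base class for all package errors."""


class InvalidBoxError(BilayerError):
    """Box lengths are non-positive, missing, or the cell is not orthorhombic."""


class ParseError(BilayerError):
    """A structure/trajectory file failed to parse.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(BilayerError):
    """A topology sidecar or output file violates its schema."""


class TrajectoryInconsistencyError(BilayerError):
    """Frames of one trajectory disagree (atom counts, time ordering)."""


class PackingFailureError(BilayerError):
    """The builder could not place atoms without overlap within its retry budget."""


class ConfigurationError(BilayerError):
    """Required declarations (head atoms, donors, roles, stages) are missing or invalid."""


class DegenerateFitError(BilayerError):
    """Plane fit requested on fewer than 3 points or on (near-)collinear points."""


class UndefinedAngleError(BilayerError):
    """Angle of a zero vector requested."""


class ParameterError(BilayerError):
    """A numeric parameter is out of its valid range."""


class BinningError(BilayerError):
    """Requested binning is incompatible with the box."""


class EmptySelectionWarning(UserWarning):
    """A selection predicate matched no atoms (not fatal)."""


class UnwrapAmbiguityWarning(UserWarning):
    """An apparent per-frame jump exceeded half the box during unwrapping."""


class LowLinearityWarning(UserWarning):
    """An MSD fit had R^2 below the linearity threshold."""
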