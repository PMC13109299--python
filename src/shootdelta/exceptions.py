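"""Exception hierarchy shared across the pipeline stages."""


class ShootDeltaError(Exception):
    """Base class for all package-specific errors."""


class CloudIOError(ShootDeltaError):
    """A point-cloud file could not be read or written."""


class CloudParseError(CloudIOError):
    """A point-cloud file was readable but malformed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class EmptyCloudError(ShootDeltaError):
    """An operation produced or received a cloud with no points."""


class DegenerateGeometryError(ShootDeltaError):
    """Too few or degenerate points for a geometric computation."""


class DegenerateMatchError(ShootDeltaError):
    """ICP found too few correspondences to solve for a rigid transform."""


class AlignmentExcludedError(ShootDeltaError):
    """A scan pair failed the registration quality gate."""


class SpecError(ShootDeltaError):
    """A synthetic tree specification is geometrically infeasible."""
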