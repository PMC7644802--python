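"""Exception hierarchy shared across the package."""


class BlockfoldError(Exception):
    """Base class for all package-specific errors."""


class InvalidTransformError(BlockfoldError):
    """Rotation matrix is not a proper orthonormal matrix."""


class DegenerateGeometryError(BlockfoldError):
    """Point configuration unsuitable for superposition (too few / collinear)."""


class InvalidNameError(BlockfoldError):
    """Module name does not conform to the naming grammar."""


class LibraryError(BlockfoldError):
    """Module library construction or validation failure."""


class IncompatiblePairError(LibraryError):
    """Pair structure does not match its declared fragments."""


class SchemaError(BlockfoldError):
    """Serialized document violates the expected schema.

    ``field`` carries a dotted path to the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class SceneError(BlockfoldError):
    """Invalid operation on a design scene."""


class CollisionError(SceneError):
    """Placement rejected because bounding spheres overlap."""

    def __init__(self, a: str, b: str):
        self.a = a
        self.b = b
        super().__init__(f"collision between {a!r} and {b!r}")


class OccupiedTerminusError(SceneError):
    """Terminus already carries a link."""


class MirrorError(SceneError):
    """Invalid mirror-group operation."""


class ValidationError(BlockfoldError):
    """A validation report contains blocking findings."""

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__(
            "validation failed: " + "; ".join(str(f) for f in self.findings)
        )


class CappingError(BlockfoldError):
    """No cap prototype available for an interface token."""


class SolverError(BlockfoldError):
    """Automated design failure."""


class NoSolutionError(SolverError):
    """Search budget exhausted without a finite-score solution."""


class IntegrityError(BlockfoldError):
    """Imported data is internally inconsistent (e.g. transform mismatch)."""
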