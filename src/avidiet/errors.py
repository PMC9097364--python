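"""Exception types shared across the package."""


class AvidietError(Exception):
    """Base class for all package errors."""


class TreeError(AvidietError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries approximate position when known."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        super().__init__(message if position is None else f"{message} (near position {position})")


class SingularMatrixError(AvidietError):
    """A matrix required to be invertible is numerically singular."""

    def __init__(self, message: str, condition_number: float | None = None):
        self.condition_number = condition_number
        if condition_number is not None:
            message = f"{message} (condition number {condition_number:.3e})"
        super().__init__(message)


class DegenerateDataError(AvidietError):
    """Input data carries no usable signal (e.g. constant trait)."""


class GroupError(AvidietError):
    """Invalid grouping structure (singleton or missing groups)."""


class GeometryError(AvidietError):
    """Degenerate or invalid geometric input."""


class CollinearPointsError(GeometryError):
    """Three claw landmarks are collinear; no unique circle exists."""


class MaterialError(AvidietError):
    """Invalid material parameters."""


class MeshError(AvidietError):
    """Invalid finite-element mesh or meshing failure."""


class SolverError(AvidietError):
    """Finite-element system could not be solved (e.g. rigid-body modes left)."""


class CompositionError(AvidietError):
    """Invalid compositional data (non-positive parts, bad closure)."""


class ClassificationError(AvidietError):
    """Diet/ecology classification failure."""


class AmbiguousDietError(ClassificationError):
    """Two diet cut-offs fired simultaneously; both category names are reported."""

    def __init__(self, categories):
        self.categories = tuple(categories)
        super().__init__(f"ambiguous diet assignment: {', '.join(self.categories)}")
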