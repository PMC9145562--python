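"""Typed exceptions raised by the antmorph pipeline.

Every malformed input maps to one of these; nothing is silently coerced.
"""


class AntmorphError(Exception):
    """Base class for all antmorph errors."""


class SchemaError(AntmorphError):
    """A required column is missing or duplicated in an input table."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class TableValidationError(AntmorphError):
    """A cell value violates the specimen-table contract (non-numeric,
    non-positive, non-finite trait, duplicate id, ...)."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class InfectionEncodingError(AntmorphError):
    """The infection column uses values outside the known synonym map."""


class DegenerateScaleError(AntmorphError):
    """A trait is constant within a species, so z-scaling is undefined."""

    def __init__(self, species: str, trait: str):
        super().__init__(
            f"trait {trait!r} is constant within species {species!r}; "
            "per-species scaling is undefined"
        )
        self.species = species
        self.trait = trait


class DesignError(AntmorphError):
    """The factorial design is rank-deficient (e.g. an empty
    species x infection cell)."""

    def __init__(self, message: str, empty_cells: list | None = None):
        super().__init__(message)
        self.empty_cells = empty_cells or []


class InsufficientDataError(AntmorphError):
    """A species x infection cell has too few specimens for moment
    estimation."""

    def __init__(self, message: str, cell: tuple | None = None):
        super().__init__(message)
        self.cell = cell


class DegenerateMomentsError(AntmorphError):
    """A group standard deviation is zero; the distribution map is
    undefined."""


class StratificationError(AntmorphError):
    """A class is too small to stratify across cross-validation folds."""


class DivergenceError(AntmorphError):
    """Neural-network training produced a non-finite loss; reduce the
    learning rate."""


class ScenarioError(AntmorphError):
    """A synthetic-data scenario specification violates its invariants."""
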